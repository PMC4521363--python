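"""Library-size adjustment, filtering, unit averaging and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeimix.preprocess import (
    adjust_library_size,
    compute_unit_averages,
    filter_snps,
    normalize_region,
    read_counts_table,
    round_half_away,
    stratify_by_region,
    trim_top_units,
)


class TestRegionNormalization:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("3UTR", "utr3"), ("utr3", "utr3"), ("5utr", "utr5"),
            ("Exonic", "exon"), ("INTRONIC", "intron"),
            ("intergenic", "intergenic"), ("upstream", "upstream"),
        ],
    )
    def test_tokens(self, token, expected):
        assert normalize_region(token) == expected

    def test_multi_label_priority(self):
        assert normalize_region("intron;3utr") == "utr3"
        assert normalize_region("exonic;intronic") == "exon"

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            normalize_region("promoter")


class TestAdjustLibrarySize:
    def test_median_sample_unchanged(self, tiny_counts):
        adj = adjust_library_size(tiny_counts)
        totals = (
            (tiny_counts.ref_count + tiny_counts.var_count)
            .groupby(tiny_counts.subject + tiny_counts.tissue).sum()
        )
        # at least one sample sits at the median and keeps scale 1
        assert np.isclose(adj["scale"], 1.0).any()

    def test_known_arithmetic(self):
        # own total twice the median: pair (6, 9) becomes (3.0, 4.5)
        df = pd.DataFrame(
            {
                "subject": ["a", "b", "c"],
                "tissue": ["t", "t", "t"],
                "gene": ["g"] * 3,
                "snp": ["r1", "r2", "r3"],
                "region": ["utr3"] * 3,
                "ref_count": [6, 4, 2],
                "var_count": [9, 26, 28],
            }
        )
        adj = adjust_library_size(df)  # totals: 15, 30, 30 -> median 30
        row = adj[adj.subject == "a"].iloc[0]
        assert row.scale == pytest.approx(2.0)
        b = adj[adj.subject == "b"].iloc[0]
        assert (b.ref_adj, b.var_adj) == (pytest.approx(4.0), pytest.approx(26.0))

    def test_identical_totals_identity(self):
        df = pd.DataFrame(
            {
                "subject": ["a", "b"], "tissue": ["t", "t"], "gene": ["g", "g"],
                "snp": ["r1", "r2"], "region": ["exon", "exon"],
                "ref_count": [10, 15], "var_count": [10, 5],
            }
        )
        adj = adjust_library_size(df)
        assert np.allclose(adj["ref_adj"], df["ref_count"])
        assert np.allclose(adj["var_adj"], df["var_count"])

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 500)),
            min_size=2, max_size=12,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_ratio_preserved(self, counts):
        df = pd.DataFrame(
            {
                "subject": [f"s{i % 3}" for i in range(len(counts))],
                "tissue": ["t0"] * len(counts),
                "gene": ["g"] * len(counts),
                "snp": [f"r{i}" for i in range(len(counts))],
                "region": ["utr3"] * len(counts),
                "ref_count": [c[0] for c in counts],
                "var_count": [c[1] for c in counts],
            }
        )
        adj = adjust_library_size(df)
        ratio_raw = df["ref_count"] / df["var_count"]
        ratio_adj = adj["ref_adj"] / adj["var_adj"]
        assert np.allclose(ratio_raw, ratio_adj, rtol=1e-12)

    def test_idempotent_once_equalized(self, tiny_counts):
        adj = adjust_library_size(tiny_counts)
        totals = (
            adj.assign(total=adj.ref_adj + adj.var_adj)
            .groupby(["subject", "tissue"])["total"].sum().to_dict()
        )
        again = adjust_library_size(
            adj.assign(ref_count=adj.ref_adj, var_count=adj.var_adj),
            library_totals=totals,
        )
        assert np.allclose(again["ref_adj"], adj["ref_adj"], rtol=1e-9)

    def test_missing_total_names_sample(self, tiny_counts):
        with pytest.raises(ValueError, match="s2"):
            adjust_library_size(tiny_counts, library_totals={("s1", "t1"): 10, ("s1", "t2"): 10})

    def test_zero_total_rejected(self, tiny_counts):
        totals = {(s, t): 100 for s, t in zip(tiny_counts.subject, tiny_counts.tissue)}
        totals[("s1", "t2")] = 0
        with pytest.raises(ValueError, match="s1/t2"):
            adjust_library_size(tiny_counts, library_totals=totals)


class TestFilterSnps:
    def test_boundary_kept_and_dropped(self, tiny_counts):
        out = filter_snps(tiny_counts)
        snps = set(out.snp)
        assert "rs2" in snps       # min(3, 100) == 3 at the boundary
        assert "rs5" not in snps   # min(2, 500) below threshold
        assert "rs4" not in snps   # intergenic excluded
        assert "rs3" in snps

    def test_empty_result_warns(self, tiny_counts):
        with pytest.warns(UserWarning):
            filter_snps(tiny_counts, min_low_allele=10_000)


class TestUnitAverages:
    def test_single_and_mean(self):
        df = pd.DataFrame(
            {
                "subject": ["s", "s", "s"], "tissue": ["t", "t", "u"],
                "gene": ["g", "g", "g"], "snp": ["r1", "r2", "r1"],
                "region": ["utr3"] * 3,
                "ref_count": [1, 1, 1], "var_count": [1, 1, 1],
                "sum_adj": [30.0, 50.0, 12.0],
            }
        )
        units = compute_unit_averages(df)
        # same gene in two tissues -> two units
        assert len(units) == 2
        tt = units[units.tissue == "t"].iloc[0]
        assert tt.mean_total == pytest.approx(40.0)
        assert tt.n_snps == 2
        assert units[units.tissue == "u"].iloc[0].mean_total == pytest.approx(12.0)


class TestTrim:
    def _units(self, n):
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "tissue": ["t"] * n,
                "gene": [f"g{i}" for i in range(n)],
                "mean_total": np.arange(n, dtype=float),
                "n_snps": [1] * n,
            }
        )

    def test_zero_fraction_keeps_all(self):
        kept, removed = trim_top_units(self._units(100), fraction=0.0)
        assert len(kept) == 100 and len(removed) == 0

    def test_one_in_thousand(self):
        kept, removed = trim_top_units(self._units(1000), fraction=0.001)
        assert len(removed) == 1
        assert removed.iloc[0].mean_total == 999.0

    def test_order_property(self):
        kept, removed = trim_top_units(self._units(50), fraction=0.1)
        assert removed["mean_total"].min() >= kept["mean_total"].max()


class TestStratify:
    def test_partition(self, tiny_counts):
        adj = adjust_library_size(filter_snps(tiny_counts))
        units = compute_unit_averages(adj)
        labels = units[["subject", "tissue", "gene"]].copy()
        labels["component"] = [0, 1, 0][: len(units)]
        strata, excluded = stratify_by_region(adj, labels)
        total = sum(len(v) for v in strata.values()) + len(excluded)
        assert total == len(adj)
        keys = list(strata)
        assert all(k[1] in ("utr3", "utr5", "exon", "intron") for k in keys)

    def test_unlabeled_unit_rejected(self, tiny_counts):
        adj = adjust_library_size(filter_snps(tiny_counts))
        labels = pd.DataFrame(
            {"subject": ["s1"], "tissue": ["t1"], "gene": ["GA"], "component": [0]}
        )
        with pytest.raises(ValueError, match="unlabelled"):
            stratify_by_region(adj, labels)


class TestIO:
    def test_roundtrip_and_validation(self, tiny_counts, tmp_path):
        p = tmp_path / "counts.tsv"
        tiny_counts.to_csv(p, sep="\t", index=False)
        df = read_counts_table(p)
        assert list(df.columns[:7]) == [
            "subject", "tissue", "gene", "snp", "region", "ref_count", "var_count"
        ]
        assert df.ref_count.dtype == np.int64

    def test_missing_column_rejected(self, tiny_counts, tmp_path):
        p = tmp_path / "bad.tsv"
        tiny_counts.drop(columns=["snp"]).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="snp"):
            read_counts_table(p)


def test_round_half_away():
    assert round_half_away(2.5) == 3.0
    assert round_half_away(-2.5) == -3.0
    assert round_half_away(2.4) == 2.0
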