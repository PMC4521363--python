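"""End-to-end orchestration: filter, adjust, group, fit, test, call, report.

The pipeline runs the four stages in order — library-size adjustment,
Poisson-mixture coverage grouping (BIC), per-stratum folded-Skellam mixture
fitting (BIC), and per-component likelihood-ratio testing — then designates
signal components, classifies SNPs, and derives the cross-tissue
consistency and read-ratio diagnostics.  All randomness descends from the
single config seed through a SeedSequence tree, so identical config + input
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import folded_mixture as fsm
from . import poisson_mixture as pmx
from . import preprocess as prep
from .abc_backend import fit_mixture_abc

__all__ = [
    "PipelineConfig",
    "RunBundle",
    "run_pipeline",
    "consistency_report",
    "ratio_percentile_table",
    "write_run_bundle",
]


@dataclasses.dataclass
class PipelineConfig:
    """Tunable knobs of the whole pipeline (defaults follow the method's
    published protocol where one exists)."""

    min_low_allele: int = 3
    exclude_regions: tuple = ("intergenic",)
    trim_fraction: float = 0.001
    poisson_k_range: tuple = (1, 10)      # inclusive (lo, hi)
    skellam_k_range: tuple = (1, 8)
    poisson_restarts: int = 3
    skellam_restarts: int = 3
    target_components: tuple | None = None  # e.g. (0,) to mimic a Comp.1-only analysis
    target_regions: tuple | None = None     # e.g. ("utr3",)
    alpha: float = 0.05
    min_effect_sd: float = 1.0
    min_test_n: int = 10
    min_stratum_size: int = 50
    rule: str = "max_prob"                 # or "threshold"
    threshold: float = 0.8
    multiple_testing: str = "bonferroni"   # or "raw"
    backend: str = "em"                    # or "abc"
    em_tol: float = 1e-6
    em_max_iter: int = 300
    seed: int = 0
    library_totals: Mapping | None = None

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 1:
            raise ValueError("trim_fraction must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("poisson_k_range", "skellam_k_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("poisson_k_range", "skellam_k_range", "exclude_regions",
                    "target_components", "target_regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("library_totals")
        return d


@dataclasses.dataclass
class StratumResult:
    component: int
    region: str
    n_snps: int
    model: fsm.FoldedSkellamMixtureModel | None
    tests: list
    signal_components: set
    skipped: bool = False


@dataclasses.dataclass
class RunBundle:
    adjusted: pd.DataFrame
    units: pd.DataFrame
    unit_labels: pd.DataFrame
    poisson_model: pmx.PoissonMixtureModel
    strata: dict
    calls: pd.DataFrame
    excluded: pd.DataFrame
    manifest: dict


def _k_iter(k_range: tuple) -> range:
    return range(int(k_range[0]), int(k_range[1]) + 1)


def run_pipeline(config: PipelineConfig, counts: pd.DataFrame) -> RunBundle:
    """Execute the full detection pipeline on an allele-count table."""
    ss = np.random.SeedSequence(config.seed)
    seed_poisson, seed_strata = ss.spawn(2)

    n_input = len(counts)
    filtered = prep.filter_snps(
        counts, min_low_allele=config.min_low_allele,
        exclude_regions=config.exclude_regions,
    )
    if filtered.empty:
        raise ValueError("no SNPs left after filtering; nothing to analyse")
    adjusted = prep.adjust_library_size(filtered, config.library_totals)

    units = prep.compute_unit_averages(adjusted)
    kept_units, trimmed_units = prep.trim_top_units(units, config.trim_fraction)
    trimmed_keys = set(map(tuple, trimmed_units[["subject", "tissue", "gene"]].to_numpy()))
    unit_key = list(map(tuple, adjusted[["subject", "tissue", "gene"]].to_numpy()))
    adjusted_kept = adjusted[[k not in trimmed_keys for k in unit_key]].copy()

    poisson_model = pmx.select_k_bic(
        kept_units["mean_total"].to_numpy(),
        _k_iter(config.poisson_k_range),
        restarts=config.poisson_restarts,
        seed=seed_poisson,
        tol=config.em_tol,
    )
    labels, _ = pmx.classify_units(poisson_model, kept_units["mean_total"].to_numpy())
    unit_labels = kept_units[["subject", "tissue", "gene"]].copy()
    unit_labels["component"] = labels

    strata_map, excluded = prep.stratify_by_region(adjusted_kept, unit_labels)
    if config.target_components is not None:
        strata_map = {k: v for k, v in strata_map.items()
                      if k[0] in set(config.target_components)}
    if config.target_regions is not None:
        wanted = {prep.normalize_region(r) for r in config.target_regions}
        strata_map = {k: v for k, v in strata_map.items() if k[1] in wanted}

    stratum_keys = sorted(strata_map)
    child_seeds = seed_strata.spawn(max(len(stratum_keys), 1))
    strata: dict = {}
    warnings_log = []
    for key, child in zip(stratum_keys, child_seeds):
        comp, region = key
        sub = strata_map[key]
        y = sub["abs_diff"].to_numpy()
        if len(sub) < config.min_stratum_size:
            strata[key] = StratumResult(comp, region, len(sub), None, [], set(), skipped=True)
            warnings_log.append(
                f"stratum {key}: {len(sub)} SNPs < min_stratum_size "
                f"{config.min_stratum_size}; left unclassified"
            )
            continue
        if config.backend == "em":
            model = fsm.select_k_bic_folded(
                y, _k_iter(config.skellam_k_range),
                restarts=config.skellam_restarts, seed=child,
                tol=config.em_tol, max_iter=config.em_max_iter,
            )
        elif config.backend == "abc":
            k_seeds = child.spawn(len(list(_k_iter(config.skellam_k_range))))
            fits = []
            for k, ks in zip(_k_iter(config.skellam_k_range), k_seeds):
                if k > len(np.unique(y)):
                    continue
                fits.append(fit_mixture_abc(y, k, seed=ks))
            model = min(fits, key=lambda m: m.bic)
        else:
            raise ValueError(f"unknown backend {config.backend!r}")
        post = fsm.posterior_probs(model, y)
        argmax = np.argmax(post, axis=1)
        tests = [
            fsm.lrt_equal_means(model, i, y[argmax == i], min_test_n=config.min_test_n)
            for i in range(model.K)
        ]
        strata[key] = StratumResult(comp, region, len(sub), model, tests, set())

    n_tested = sum(t.tested for s in strata.values() for t in s.tests)
    alpha_eff = config.alpha
    if config.multiple_testing == "bonferroni" and n_tested > 0:
        alpha_eff = config.alpha / n_tested
    elif config.multiple_testing not in ("bonferroni", "raw"):
        raise ValueError(f"unknown multiple_testing {config.multiple_testing!r}")

    call_frames = []
    for key in stratum_keys:
        res = strata[key]
        sub = strata_map[key].reset_index(drop=True)
        base = sub[
            ["subject", "tissue", "gene", "snp", "region", "component",
             "ref_count", "var_count", "ref_adj", "var_adj", "abs_diff"]
        ].copy()
        base["ratio"] = (
            np.maximum(base["ref_count"], base["var_count"])
            / np.minimum(base["ref_count"], base["var_count"])
        )
        base["diff_sign"] = np.sign(base["ref_adj"] - base["var_adj"]).astype(int)
        if res.skipped:
            base["skellam_component"] = -1
            base["signal_prob"] = np.nan
            base["designation"] = "unclassified"
            base["posteriors"] = ""
        else:
            res.signal_components = fsm.designate_signal_components(
                res.model, res.tests, alpha=alpha_eff,
                min_effect_sd=config.min_effect_sd,
            )
            cls = fsm.classify_snps(
                res.model, sub["abs_diff"].to_numpy(), res.signal_components,
                rule=config.rule, threshold=config.threshold, alpha=config.alpha,
            )
            base["skellam_component"] = cls["component"].to_numpy()
            base["signal_prob"] = cls["signal_prob"].to_numpy()
            base["designation"] = cls["designation"].to_numpy()
            post_cols = [c for c in cls.columns if c.startswith("post_")]
            base["posteriors"] = [
                ";".join(f"{v:.6g}" for v in row)
                for row in cls[post_cols].to_numpy()
            ]
        base["aei_p80"] = base["signal_prob"] >= 0.80
        base["aei_p99"] = base["signal_prob"] >= 0.99
        call_frames.append(base)
    if call_frames:
        calls = pd.concat(call_frames, ignore_index=True)
        calls = calls.sort_values(
            ["component", "region", "subject", "tissue", "gene", "snp"]
        ).reset_index(drop=True)
    else:
        calls = pd.DataFrame()

    n_excluded_regions = int(len(excluded))
    manifest = {
        "config": config.to_dict(),
        "stages": {
            "n_input": n_input,
            "n_filtered_out": n_input - len(filtered),
            "n_trimmed_snps": len(adjusted) - len(adjusted_kept),
            "n_excluded_regions": n_excluded_regions,
            "n_stratified": int(sum(len(v) for v in strata_map.values())),
            "n_units": len(units),
            "n_units_trimmed": len(trimmed_units),
        },
        "poisson_model": {
            "K": poisson_model.K,
            "weights": [float(w) for w in poisson_model.weights],
            "means": [float(m) for m in poisson_model.means],
            "loglik": poisson_model.loglik,
            "bic": poisson_model.bic,
            "n_obs": poisson_model.n_obs,
        },
        "n_component_tests": n_tested,
        "alpha_effective": alpha_eff,
        "strata": {
            f"{k[0]}_{k[1]}": {
                "n_snps": s.n_snps,
                "skipped": s.skipped,
                "K": s.model.K if s.model else None,
                "loglik": s.model.loglik if s.model else None,
                "bic": s.model.bic if s.model else None,
                "signal_components": sorted(s.signal_components),
            }
            for k, s in strata.items()
        },
        "warnings": warnings_log,
        "seed": config.seed,
    }
    return RunBundle(
        adjusted=adjusted_kept, units=units, unit_labels=unit_labels,
        poisson_model=poisson_model, strata=strata, calls=calls,
        excluded=excluded, manifest=manifest,
    )


def consistency_report(calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-tissue agreement of per-SNP designations within subjects.

    For every (subject, snp) observed in at least two tissues, counts the
    tissues where the SNP is expressed (present in the calls) and where it
    is designated imbalanced; the designation is *consistent* when the SNP
    shows imbalance in at least half of its expressed tissues.
    """
    grouped = calls.groupby(["subject", "snp"])
    rows = []
    for (subject, snp), sub in grouped:
        n_expr = sub["tissue"].nunique()
        if n_expr < 2:
            continue
        n_aei = sub.loc[sub["designation"] == "AEI", "tissue"].nunique()
        rows.append(
            {
                "subject": subject,
                "snp": snp,
                "n_regions_expressed": n_expr,
                "n_regions_aei": n_aei,
                "consistent": n_aei >= -(-n_expr // 2),
            }
        )
    return pd.DataFrame(
        rows, columns=["subject", "snp", "n_regions_expressed", "n_regions_aei", "consistent"]
    )


def ratio_percentile_table(calls: pd.DataFrame, group_col: str = "designation") -> pd.DataFrame:
    """Percentiles of raw absolute read ratios max(R,V)/min(R,V) per group.

    Deciles use linear interpolation between order statistics; min and max
    flank them.  Raw counts are used — the ratio is invariant to library
    scaling.
    """
    ratios = (
        np.maximum(calls["ref_count"], calls["var_count"])
        / np.minimum(calls["ref_count"], calls["var_count"])
    )
    qs = np.arange(10, 100, 10)
    rows = []
    for group, idx in calls.groupby(group_col).groups.items():
        r = ratios.loc[idx].to_numpy()
        row = {"group": group, "n": len(r), "min": float(np.min(r))}
        for q in qs:
            row[f"p{q}"] = float(np.percentile(r, q))
        row["max"] = float(np.max(r))
        rows.append(row)
    return pd.DataFrame(rows)


def write_run_bundle(bundle: RunBundle, outdir) -> None:
    """Write the pipeline outputs as TSV/JSON under ``outdir``."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    prep.write_table(bundle.adjusted, out / "adjusted.tsv")
    pm = bundle.poisson_model
    pmodel = pd.DataFrame(
        {
            "component": np.arange(pm.K),
            "weight": pm.weights,
            "mean": pm.means,
        }
    )
    prep.write_table(pmodel, out / "poisson_model.tsv")
    models_dir = out / "skellam_models"
    models_dir.mkdir(exist_ok=True)
    for (comp, region), res in bundle.strata.items():
        if res.model is None:
            continue
        tests = {t.component: t for t in res.tests}
        rows = []
        for i, c in enumerate(res.model.components):
            t = tests.get(i)
            rows.append(
                {
                    "component": i,
                    "weight": c.weight,
                    "lambda_1": c.lambda_hi,
                    "lambda_2": c.lambda_lo,
                    "L0": t.L0 if t and t.tested else np.nan,
                    "L1": t.L1 if t and t.tested else np.nan,
                    "stat": t.stat if t and t.tested else np.nan,
                    "pvalue": t.pvalue if t and t.tested else np.nan,
                    "n_snps": t.n_assigned if t else 0,
                    "signal": i in res.signal_components,
                }
            )
        prep.write_table(pd.DataFrame(rows), models_dir / f"{comp}_{region}.tsv")
    prep.write_table(bundle.calls, out / "calls.tsv")
    prep.write_table(consistency_report(bundle.calls), out / "consistency.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=float)
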