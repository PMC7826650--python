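"""Study orchestration: feature tables -> Gaussianisation -> ICC/RC -> comparisons.

A *dataset* is one two-visit feature table (one MR sequence, with or without
image normalisation). Each dataset is analysed twice — on original feature
values and on Box-Cox transformed values — so four sequences yield the full
4 x {raw, normalised} x {original, boxcox} = 16 dataset combinations.

All randomness flows from a single top-level seed fanned out per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import compare_iccs, volume_confounding
from .gaussianisation import STATUS_PRE, classify_features, records_frame
from .repeatability import IccResult, icc_1_1, icc_cov_across_datasets, rc
from .synthetic import RandomEffectsSpec, simulate_multifeature_table
from .tables import FeatureTable

BOXCOX_SUFFIX = "+boxcox"
ORIGINAL_SUFFIX = "+original"


@dataclass
class RunConfig:
    """Configuration of one study run."""

    mode: str = "synthetic"  # synthetic | feature_tables | images
    sequences: list[str] = field(default_factory=lambda: ["seqA", "seqB"])
    table_paths: dict[str, str] = field(default_factory=dict)  # sequence -> long CSV
    normalise: bool = True
    bin_width: float = 5.0
    alpha: float = 0.05
    n_features_bonferroni: int | None = None  # default: features in the panel
    lambda_method: str = "ppcc"
    seed: int = 0
    n_lesions: int = 134
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mode not in ("synthetic", "feature_tables", "images"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.mode == "feature_tables" and not self.table_paths:
            raise ValueError("feature_tables mode requires table_paths")


@dataclass
class StudyReport:
    """All result tables of one run, plus provenance."""

    icc_rc: pd.DataFrame  # dataset, feature, icc, ci, rc, ci, n
    transform_counts: pd.DataFrame  # dataset x (gaussian_pre, gaussian_post, never)
    transform_records: pd.DataFrame
    comparisons: pd.DataFrame  # dataset_a, dataset_b, feature, z_diff, ci, p, significant
    icc_cov: pd.DataFrame  # feature, cov
    volume_correlation: pd.DataFrame
    provenance: dict

    def comparison_counts(self) -> pd.DataFrame:
        """Significant-feature counts per dataset pair (the '38/105' numbers)."""
        if self.comparisons.empty:
            return pd.DataFrame(columns=["dataset_a", "dataset_b", "n_significant", "n_features"])
        g = self.comparisons.groupby(["dataset_a", "dataset_b"])
        return g["significant"].agg(n_significant="sum", n_features="count").reset_index()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def synthetic_datasets(config: RunConfig) -> dict[str, FeatureTable]:
    """Two-visit tables per sequence with known variance components.

    Each sequence gets a panel of features spanning high to modest true ICC,
    half of them skewed through an inverse Box-Cox map (lambda 0 or 0.5),
    emulating the mix of Gaussian and non-Gaussian radiomic features.
    """
    panel = [
        # (name, sigma_b, sigma_w, lambda_skew)
        ("volume_like", 3.0, 0.3, None),
        ("texture_high_icc", 2.0, 0.7, None),
        ("texture_mid_icc", 1.0, 1.0, None),
        ("skewed_lognormal", 1.5, 0.8, 0.0),
        ("skewed_sqrt", 1.5, 0.8, 0.5),
        ("low_icc", 0.6, 1.0, None),
    ]
    datasets: dict[str, FeatureTable] = {}
    for s_i, seq in enumerate(config.sequences):
        specs = []
        for f_i, (name, sb, sw, lam) in enumerate(panel):
            specs.append(
                RandomEffectsSpec(
                    mu=10.0,
                    sigma_b=sb,
                    sigma_w=sw,
                    n_lesions=config.n_lesions,
                    lambda_skew=lam,
                    seed=_stage_seed(config.seed, f"sim:{s_i}:{f_i}"),
                    name=name,
                )
            )
        datasets[seq] = simulate_multifeature_table(specs)
    return datasets


def load_datasets(config: RunConfig) -> dict[str, FeatureTable]:
    return {seq: FeatureTable.read_long(path) for seq, path in config.table_paths.items()}


def analyse_datasets(
    datasets: dict[str, FeatureTable], config: RunConfig
) -> StudyReport:
    """Run the statistical workflow on paired two-visit feature tables."""
    if not datasets:
        raise ValueError("no datasets supplied")
    icc_rows, rec_frames, count_rows, cmp_rows = [], [], [], []
    icc_lookup: dict[tuple[str, str], IccResult] = {}
    per_variant_tables: dict[str, FeatureTable] = {}

    for ds_name, table in datasets.items():
        paired = table.paired()
        if paired.n_lesions < 2:
            raise ValueError(f"dataset {ds_name!r} has < 2 paired lesions")
        records, transformed, counts = classify_features(
            paired, config.alpha, config.n_features_bonferroni, config.lambda_method
        )
        rec = records_frame(records)
        rec.insert(0, "dataset", ds_name)
        rec_frames.append(rec)
        count_rows.append({"dataset": ds_name, **counts})

        for variant, tab in ((ORIGINAL_SUFFIX, paired), (BOXCOX_SUFFIX, transformed)):
            key = ds_name + variant
            per_variant_tables[key] = tab
            status = {r.feature_name: r.status for r in records}
            for feat in tab.feature_names:
                mat = tab.visit_matrix(feat)
                try:
                    icc_res = icc_1_1(mat)
                    rc_res = rc(mat)
                except ValueError:
                    continue
                icc_lookup[(key, feat)] = icc_res
                icc_rows.append(
                    {
                        "dataset": key,
                        "feature": feat,
                        "status": status.get(feat, STATUS_PRE),
                        "icc": icc_res.icc,
                        "icc_ci_low": icc_res.ci_low,
                        "icc_ci_high": icc_res.ci_high,
                        "rc": rc_res.rc,
                        "rc_ci_low": rc_res.ci_low,
                        "rc_ci_high": rc_res.ci_high,
                        "wsd": rc_res.wsd,
                        "n": icc_res.n_subjects,
                    }
                )

    # pair-wise Fisher-Z comparisons on the Box-Cox variants, plus the
    # original-vs-boxcox contrast within each dataset
    panel_sizes = {k: len(t.feature_names) for k, t in per_variant_tables.items()}
    m_default = config.n_features_bonferroni

    def _compare(key_a: str, key_b: str) -> None:
        feats = [
            f
            for f in per_variant_tables[key_a].feature_names
            if (key_a, f) in icc_lookup and (key_b, f) in icc_lookup
        ]
        m = m_default if m_default is not None else max(panel_sizes[key_a], panel_sizes[key_b])
        for feat in feats:
            a, b = icc_lookup[(key_a, feat)], icc_lookup[(key_b, feat)]
            if not (-1 < a.icc < 1 and -1 < b.icc < 1):
                continue
            c = compare_iccs(a, b, config.alpha, m, feature_name=feat)
            cmp_rows.append(
                {
                    "dataset_a": key_a,
                    "dataset_b": key_b,
                    "feature": feat,
                    "z_diff": c.z_diff,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p": c.p,
                    "significant": c.significant,
                }
            )

    for ds_name in datasets:
        _compare(ds_name + ORIGINAL_SUFFIX, ds_name + BOXCOX_SUFFIX)
    for a_name, b_name in combinations(datasets, 2):
        _compare(a_name + BOXCOX_SUFFIX, b_name + BOXCOX_SUFFIX)

    icc_rc = pd.DataFrame(icc_rows)
    cov_rows = []
    if not icc_rc.empty:
        for feat, grp in icc_rc[icc_rc["dataset"].str.endswith(BOXCOX_SUFFIX)].groupby("feature"):
            if len(grp) >= 2 and grp["icc"].mean() != 0:
                cov_rows.append({"feature": feat, "icc_cov": icc_cov_across_datasets(grp["icc"])})

    vol_rows = []
    for ds_name, table in datasets.items():
        ref = "shape_mesh_volume"
        if ref in table.feature_names:
            for feat, rho in volume_confounding(table.paired(), ref).items():
                vol_rows.append({"dataset": ds_name, "feature": feat, "abs_spearman": rho})

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "alpha": config.alpha,
        "lambda_method": config.lambda_method,
        "datasets": sorted(datasets),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in vars(config).items() if k != "output_dir"},
                sort_keys=True,
                default=str,
            ).encode()
        ).hexdigest(),
    }
    return StudyReport(
        icc_rc=icc_rc,
        transform_counts=pd.DataFrame(count_rows),
        transform_records=pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame(),
        comparisons=pd.DataFrame(cmp_rows),
        icc_cov=pd.DataFrame(cov_rows),
        volume_correlation=pd.DataFrame(vol_rows),
        provenance=provenance,
    )


def run_study(config: RunConfig) -> StudyReport:
    """Execute the configured workflow end to end."""
    if config.mode == "synthetic":
        datasets = synthetic_datasets(config)
    elif config.mode == "feature_tables":
        datasets = load_datasets(config)
    else:
        raise NotImplementedError(
            "images mode is driven through the CLI stages (fit-t1, extract) "
            "followed by feature_tables analysis"
        )
    report = analyse_datasets(datasets, config)
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Write all report tables as CSV plus a provenance JSON (atomically)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frames = {
        "icc_rc.csv": report.icc_rc,
        "transform_counts.csv": report.transform_counts,
        "transform_records.csv": report.transform_records,
        "comparisons.csv": report.comparisons,
        "comparison_counts.csv": report.comparison_counts(),
        "icc_cov.csv": report.icc_cov,
        "volume_correlation.csv": report.volume_correlation,
    }
    for name, frame in frames.items():
        tmp = out / (name + ".tmp")
        frame.to_csv(tmp, index=False)
        tmp.replace(out / name)
        written.append(out / name)
    tmp = out / "provenance.json.tmp"
    tmp.write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
    tmp.replace(out / "provenance.json")
    written.append(out / "provenance.json")
    return written
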