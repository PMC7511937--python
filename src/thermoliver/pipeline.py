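"""End-to-end weekly detection experiment and group-comparison statistics.

The experiment mirrors the study's analysis: per mouse and week the nine
ROI features are extracted (multiple images per mouse aggregated), the
feature tables from week 2 through the analysis week W are concatenated
per mouse into a 9·(W−1)-dimensional vector, standardized, embedded to
2-D with t-SNE, clustered with k-means (k = 2), and the cluster
assignment is scored against the true diet groups under the best
cluster-to-label permutation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tio
from .cluster import DetectionResult, detection_rate, kmeans
from .features import DEFAULT_OFFSET, extract_features
from .io import FEATURE_NAMES, ROI, WeeklyFeatureTable
from .synthetic import SyntheticCohortSpec, generate_map, mouse_ids
from .tsne import EmbeddingConfig, tsne

AGGREGATES = ("mean", "median", "first")


@dataclass
class ExperimentConfig:
    """Settings of a full detection run over a cohort manifest."""

    manifest: str
    roi: ROI | None = None
    offset: tuple[int, int] = DEFAULT_OFFSET
    aggregate: str = "mean"
    start_week: int = 2
    analysis_weeks: tuple[int, ...] = (2, 3, 4, 5)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    kmeans_restarts: int = 10
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregate not in AGGREGATES:
            raise ValueError(f"aggregate must be one of {AGGREGATES}")
        if not self.analysis_weeks:
            raise ValueError("analysis week range is empty")


@dataclass
class WeeklyDetectionReport:
    """Per-analysis-week detection outcomes plus a config echo."""

    weeks: dict[int, dict]
    config: dict
    version: str


def extract_cohort_features(
    manifest: pd.DataFrame,
    image_root: str | Path = ".",
    roi: ROI | None = None,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    aggregate: str = "mean",
) -> dict[int, WeeklyFeatureTable]:
    """Per-week feature tables from a manifest of image files.

    Multiple images of the same (mouse, week) are reduced to one feature
    vector by the chosen aggregation rule.
    """
    image_root = Path(image_root)
    rows = []
    for rec in manifest.itertuples(index=False):
        T = tio.read_map(image_root / rec.image_path)
        fv = extract_features(T, roi=roi, offset=offset)
        rows.append({"mouse_id": rec.mouse_id, "group": rec.group, "week": int(rec.week),
                     **dict(zip(FEATURE_NAMES, fv.to_array()))})
    long = pd.DataFrame.from_records(rows)
    return _aggregate_weekly(long, aggregate)


def _aggregate_weekly(long: pd.DataFrame, aggregate: str) -> dict[int, WeeklyFeatureTable]:
    if aggregate not in AGGREGATES:
        raise ValueError(f"aggregate must be one of {AGGREGATES}")
    tables: dict[int, WeeklyFeatureTable] = {}
    for week, sub in long.groupby("week"):
        grouped = sub.groupby(["mouse_id", "group"], as_index=False)
        if aggregate == "mean":
            agg = grouped[list(FEATURE_NAMES)].mean()
        elif aggregate == "median":
            agg = grouped[list(FEATURE_NAMES)].median()
        else:
            agg = grouped[list(FEATURE_NAMES)].first()
        tables[int(week)] = WeeklyFeatureTable(int(week), agg.reset_index(drop=True))
    return tables


def concatenate_weeks(
    tables: dict[int, WeeklyFeatureTable] | list[WeeklyFeatureTable],
    through_week: int,
    start_week: int = 2,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-mouse concatenation of feature vectors from start_week..through_week.

    Returns (X, mouse_ids, group_labels) with X of shape
    N × 9·(through_week − start_week + 1), mice sorted by id. All weeks
    in the range must be present and share the same mouse set.
    """
    if isinstance(tables, list):
        tables = {t.week: t for t in tables}
    weeks = list(range(start_week, through_week + 1))
    missing = [w for w in weeks if w not in tables]
    if missing:
        raise ValueError(f"missing feature tables for week(s) {missing}")
    ref = sorted(tables[weeks[0]].mouse_ids)
    for w in weeks[1:]:
        ids = sorted(tables[w].mouse_ids)
        if ids != ref:
            raise ValueError(
                f"mouse sets differ between week {weeks[0]} and week {w}: "
                f"missing {sorted(set(ref) ^ set(ids))}"
            )
    blocks = []
    for w in weeks:
        df = tables[w].data.set_index("mouse_id").loc[ref]
        blocks.append(df.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float))
    groups = tables[weeks[0]].data.set_index("mouse_id").loc[ref, "group"].to_numpy()
    return np.hstack(blocks), ref, groups


def detect_week(
    tables: dict[int, WeeklyFeatureTable],
    through_week: int,
    start_week: int = 2,
    embedding: EmbeddingConfig | None = None,
    kmeans_seed: int = 0,
    kmeans_restarts: int = 10,
) -> tuple[DetectionResult, np.ndarray, float]:
    """Concatenate→embed→cluster→score for one analysis week.

    Returns (DetectionResult, 2-D coordinates, final KL).
    """
    X, _, groups = concatenate_weeks(tables, through_week, start_week)
    emb = tsne(X, embedding or EmbeddingConfig())
    assignments, centroids, _ = kmeans(
        emb.coords, k=2, seed=kmeans_seed, restarts=kmeans_restarts
    )
    result = detection_rate(assignments, groups, centroids=centroids)
    return result, emb.coords, emb.final_kl


def run_experiment(config: ExperimentConfig) -> WeeklyDetectionReport:
    """Run the weekly detection experiment from a manifest on disk.

    Writes ``report.json`` (and a run log) into ``config.out_dir`` when
    set. Deterministic under the config's seed.
    """
    manifest_path = Path(config.manifest)
    manifest = tio.read_manifest(manifest_path)
    tables = extract_cohort_features(
        manifest,
        image_root=manifest_path.parent,
        roi=config.roi,
        offset=config.offset,
        aggregate=config.aggregate,
    )
    embedding = EmbeddingConfig(**{**asdict(config.embedding), "seed": config.seed})
    weeks_out: dict[int, dict] = {}
    for W in config.analysis_weeks:
        result, coords, final_kl = detect_week(
            tables,
            W,
            start_week=config.start_week,
            embedding=embedding,
            kmeans_seed=config.seed,
            kmeans_restarts=config.kmeans_restarts,
        )
        _, ids, groups = concatenate_weeks(tables, W, config.start_week)
        weeks_out[W] = {
            "detection_rate": result.detection_rate,
            "n_correct": result.n_correct,
            "N": len(ids),
            "dimension": 9 * (W - config.start_week + 1),
            "mouse_ids": ids,
            "groups": groups.tolist(),
            "assignments": result.assignments.tolist(),
            "centroids": result.centroids.tolist(),
            "coords": coords.tolist(),
            "final_kl": final_kl,
        }
    from . import __version__

    cfg = asdict(config)
    cfg["roi"] = asdict(config.roi) if config.roi else None
    report = WeeklyDetectionReport(weeks=weeks_out, config=cfg, version=__version__)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump({"weeks": {str(k): v for k, v in weeks_out.items()},
                       "config": cfg, "version": report.version}, fh, indent=2)
        _write_run_log(out, config, manifest_path)
    return report


def _write_run_log(out: Path, config: ExperimentConfig, manifest_path: Path) -> None:
    digest = hashlib.sha256(manifest_path.read_bytes()).hexdigest()
    log = {
        "stage": "run_experiment",
        "seed": config.seed,
        "analysis_weeks": list(config.analysis_weeks),
        "manifest": str(manifest_path),
        "manifest_sha256": digest,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)


def compare_groups(a, b) -> tuple[float, float]:
    """Mann–Whitney rank-sum comparison of two samples.

    Returns (U statistic of the first sample, two-sided p). Midranks
    resolve ties. When both samples have ≤ 10 observations the p-value
    is exact, from full enumeration of label arrangements:
    p = P(|U − n1·n2/2| ≥ |U_obs − n1·n2/2|). Larger samples fall back
    to the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if n1 <= 10 and n2 <= 10:
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = 0
        base = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - base
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        p = hits / comb(n1 + n2, n1)
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return float(u_obs), float(min(p, 1.0))


def compare_feature_tables(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature rank-sum comparison of two feature tables.

    Each input needs the nine feature columns; returns one row per
    feature with the U statistic and two-sided p-value.
    """
    rows = []
    for name in FEATURE_NAMES:
        u, p = compare_groups(table_a[name], table_b[name])
        rows.append({"feature": name, "U": u, "p_value": p})
    return pd.DataFrame(rows)


def simulate_weekly_tables(
    spec: SyntheticCohortSpec,
    roi: ROI | None = None,
    offset: tuple[int, int] = DEFAULT_OFFSET,
) -> dict[int, WeeklyFeatureTable]:
    """Feature tables of a synthetic cohort computed in memory (no files)."""
    rows = []
    for mid, group, idx in mouse_ids(spec):
        for week in spec.weeks:
            T = generate_map(spec, group, week, mouse_index=idx)
            fv = extract_features(T, roi=roi, offset=offset)
            rows.append({"mouse_id": mid, "group": group, "week": int(week),
                         **dict(zip(FEATURE_NAMES, fv.to_array()))})
    return _aggregate_weekly(pd.DataFrame.from_records(rows), "first")


def make_figures(report: WeeklyDetectionReport, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """One embedding scatter per analysis week: clusters colored, centroids ×.

    Returns the list of files written; filenames are deterministic.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for W in sorted(report.weeks):
        entry = report.weeks[W]
        coords = np.asarray(entry["coords"])
        assignments = np.asarray(entry["assignments"])
        centroids = np.asarray(entry["centroids"])
        groups = np.asarray(entry["groups"])
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for c, color in zip(np.unique(assignments), ("tab:blue", "tab:orange")):
            sel = assignments == c
            ax.scatter(coords[sel, 0], coords[sel, 1], s=60, facecolors="none",
                       edgecolors=color, linewidths=1.5, label=f"cluster {c}")
        for g, marker in zip(np.unique(groups), ("o", "s")):
            sel = groups == g
            ax.scatter(coords[sel, 0], coords[sel, 1], s=12, marker=marker,
                       color="black", label=g)
        ax.scatter(centroids[:, 0], centroids[:, 1], marker="x", s=90,
                   color="red", label="centroid")
        ax.set_title(f"week {W}: detection rate {entry['detection_rate']:.0%}")
        ax.legend(fontsize=7)
        path = out_dir / f"embedding_week{W}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        files.append(path)
    return files
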