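"""Layer-wise statistics: VOI tables, discrimination tests, clustering, EAE.

The analysis mirrors a standard small-animal DTI workflow: per-animal,
per-dataset, per-layer mean metrics are collected into a tidy VOI table;
layer discrimination in healthy animals is tested with repeated-measures
ANOVA (Greenhouse–Geisser corrected when sphericity fails, generalized η²
effect size) or the Friedman test (Kendall's W) when per-layer normality
fails, with paired post-hoc tests adjusted by the Benjamini–Hochberg–
Yekutieli FDR procedure; unsupervised layer classification uses k-medoids
(PAM, k = 3, Euclidean) scored against the anatomical truth by the adjusted
Rand index; and group differences (EAE vs control) in the molecular layer
are tested with unpaired t or rank-sum tests, unadjusted.

Test selection ("as appropriate") is operationalised as Shapiro–Wilk
normality at α = 0.05 per cell and Levene's test at α = 0.05 for variance
homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .phantom import DWIDataset, GM_LAYERS, LABEL_CODES

__all__ = [
    "TestResult",
    "ClusterResult",
    "AnalysisOptions",
    "voi_means_from_maps",
    "extract_voi_table",
    "standard_dataset_masks",
    "reconstruct_standard_datasets",
    "compare_layers",
    "bhy_adjust",
    "pam_cluster",
    "adjusted_rand_index",
    "misclassification_count",
    "eae_compare",
    "run_full_analysis",
]

DATASET_LABELS = ("B1000-12Dir", "B1000-22Dir", "B2700-12Dir", "B2700-22Dir", "B2700-43Dir")
DTI_METRICS = ("FA", "MD", "AD", "RD")


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    effect_size_category: str | None = None
    comparison: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "effect_size_category": self.effect_size_category,
            "comparison": self.comparison,
        }


@dataclass
class ClusterResult:
    assignments: np.ndarray
    medoid_indices: np.ndarray
    objective: float
    cost_history: list[float] = field(default_factory=list)
    ari: float | None = None
    n_misclassified: int | None = None


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis knobs: clustering features, scaling, significance level."""

    features: tuple[str, ...] = ("FA", "MD", "RD")
    standardize: bool = False
    alpha: float = 0.05
    fit_dki: bool = False


# ---------------------------------------------------------------------------
# VOI extraction and dataset reconstruction
# ---------------------------------------------------------------------------


def voi_means_from_maps(
    maps: dict[str, np.ndarray],
    labelmap: np.ndarray,
    labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Arithmetic VOI mean of each metric map (NaN voxels excluded, counted)."""
    if labels is None:
        labels = {n: c for n, c in LABEL_CODES.items() if n != "background"}
    rows = []
    for name, code in labels.items():
        mask = labelmap == code
        if not mask.any():
            raise ValueError(f"VOI {name!r} has no voxels")
        row: dict = {"layer": name, "n_voxels": int(mask.sum())}
        for metric, arr in maps.items():
            vals = arr[mask]
            n_undef = int(np.count_nonzero(~np.isfinite(vals)))
            row[metric] = float(np.nanmean(vals)) if n_undef < vals.size else np.nan
            row[f"{metric}_n_undefined"] = n_undef
        rows.append(row)
    return pd.DataFrame(rows)


def standard_dataset_masks(
    scheme, threshold: float = 30.0
) -> dict[str, np.ndarray]:
    """Per-volume boolean masks for the five reconstructed analysis datasets.

    The b=2700 shell is greedily subsampled to 22 and 12 directions and the
    b=1000 shell to 12; each reconstructed dataset keeps its shell's b=0
    volumes.  Labels follow the B{b}-{n}Dir convention.  Deterministic for a
    given scheme, so the masks can be computed once and reused across the
    animals of a cohort.
    """
    from .schemes import DirectionSet, subsample_directions

    bvals = scheme.bvals
    # attach each run of b=0 volumes to the shell that follows it
    shell_vols: dict[float, list[int]] = {}
    shell_b0: dict[float, list[int]] = {}
    pending: list[int] = []
    for i, b in enumerate(bvals):
        if b == 0:
            pending.append(i)
        else:
            if pending:
                shell_b0.setdefault(b, []).extend(pending)
                pending = []
            shell_b0.setdefault(b, [])
            shell_vols.setdefault(b, []).append(i)
    targets = {1000.0: (22, 12), 2700.0: (43, 22, 12)}
    out: dict[str, np.ndarray] = {}
    for b, vol_idx in shell_vols.items():
        dirs = DirectionSet(scheme.bvecs[vol_idx], b, f"B{b:.0f}-{len(vol_idx)}Dir")
        wanted = [n for n in targets.get(b, ()) if n <= dirs.ndir]
        if dirs.ndir not in wanted:
            wanted.insert(0, dirs.ndir)
        for n in wanted:
            label = f"B{b:.0f}-{n}Dir"
            sub = dirs if n == dirs.ndir else subsample_directions(dirs, n, threshold, label)
            # map surviving vectors back to volume indices (exact subset)
            keep = [
                vol_idx[j]
                for j in range(dirs.ndir)
                if any(np.array_equal(dirs.vectors[j], v) for v in sub.vectors)
            ]
            mask = np.zeros(len(bvals), dtype=bool)
            mask[shell_b0.get(b, [])] = True
            mask[keep] = True
            out[label] = mask
    return out


def reconstruct_standard_datasets(
    dataset: DWIDataset, threshold: float = 30.0
) -> dict[str, DWIDataset]:
    """Derive the five analysis datasets from a two-shell acquisition."""
    return {
        label: dataset.subset(mask, label)
        for label, mask in standard_dataset_masks(dataset.scheme, threshold).items()
    }


def extract_voi_table(
    cohort_maps: dict[tuple[str, str, str], dict[str, np.ndarray]],
    labelmap: np.ndarray,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy VOI table from {(animal_id, group, dataset_label): metric maps}."""
    frames = []
    for (animal_id, group, dlabel), maps in cohort_maps.items():
        df = voi_means_from_maps(maps, labelmap)
        df.insert(0, "animal_id", animal_id)
        df.insert(1, "group", group)
        df.insert(2, "dataset_label", dlabel)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def bhy_adjust(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment (harmonic-sum correction)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def _effect_category(value: float, name: str) -> str:
    if name == "ng2":
        return "large" if value > 0.140 else "moderate"
    return "large" if value > 0.800 else "moderate"  # Kendall's W


def compare_layers(
    table: pd.DataFrame,
    metric: str,
    dataset_label: str,
    layers: tuple[str, ...] = GM_LAYERS,
    alpha: float = 0.05,
) -> tuple[TestResult, list[TestResult]]:
    """Repeated-measures layer discrimination for one metric and dataset.

    Chooses rm-ANOVA (all per-layer Shapiro–Wilk p ≥ α) with GG correction
    when Mauchly's test fails and generalized η², else Friedman with
    Kendall's W.  Post-hoc paired t / Wilcoxon signed-rank tests are
    BHY-adjusted.
    """
    import pingouin as pg

    sub = table[(table["dataset_label"] == dataset_label) & table["layer"].isin(layers)]
    wide = sub.pivot(index="animal_id", columns="layer", values=metric)[list(layers)]
    if wide.isna().any().any():
        raise ValueError("unbalanced or missing layer rows")
    n = len(wide)
    if n < 3:
        raise ValueError("need at least 3 animals")

    def _shapiro_ok(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return True  # constant cell: treat as (degenerately) normal
        return stats.shapiro(x)[1] >= alpha

    normal = all(_shapiro_ok(wide[l].to_numpy()) for l in layers)
    long = wide.reset_index().melt(id_vars="animal_id", var_name="layer", value_name="y")

    if normal and long["y"].nunique() > 1:
        aov = pg.rm_anova(
            data=long, dv="y", within="layer", subject="animal_id",
            correction="auto", effsize="ng2", detailed=False,
        )
        row = aov.iloc[0]
        p = float(row["p_unc"])
        for gg_col in ("p_GG_corr", "p-GG-corr"):  # GG correction when sphericity fails
            if gg_col in aov.columns and np.isfinite(row[gg_col]):
                p = float(row[gg_col])
                break
        es = float(row["ng2"])
        omnibus = TestResult(
            "rm-ANOVA", float(row["F"]), p, None, es, "ng2",
            _effect_category(es, "ng2"), f"{metric}@{dataset_label}",
        )
    elif long["y"].nunique() > 1:
        fr = pg.friedman(data=long, dv="y", within="layer", subject="animal_id")
        row = fr.iloc[0]
        es = float(row["W"])
        omnibus = TestResult(
            "Friedman", float(row["Q"]), float(row["p_unc"]), None, es, "W",
            _effect_category(es, "W"), f"{metric}@{dataset_label}",
        )
    else:  # all values identical: no layer effect
        omnibus = TestResult(
            "rm-ANOVA", 0.0, 1.0, None, 0.0, "ng2", "moderate", f"{metric}@{dataset_label}"
        )

    pairs = [(a, b) for i, a in enumerate(layers) for b in layers[i + 1 :]]
    raw, results = [], []
    for a, b in pairs:
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        d = x - y
        if np.ptp(d) == 0:
            method, stat, p = ("paired t", 0.0, 1.0)
        elif normal:
            stat, p = stats.ttest_rel(x, y)
            method = "paired t"
        else:
            stat, p = stats.wilcoxon(x, y)
            method = "Wilcoxon signed-rank"
        raw.append(p)
        results.append((method, float(stat), float(p), f"{a} vs {b}"))
    adj = bhy_adjust(raw)
    posthoc = [
        TestResult(m, s, p, float(pa), comparison=f"{metric}@{dataset_label}: {c}")
        for (m, s, p, c), pa in zip(results, adj)
    ]
    return omnibus, posthoc


def eae_compare(
    table: pd.DataFrame,
    metric: str,
    dataset_label: str,
    layer: str = "ML",
    alpha: float = 0.05,
) -> TestResult:
    """Unpaired EAE-vs-control comparison in one layer; raw p, no adjustment.

    Shapiro–Wilk per group selects t-test (Levene choosing homo- vs
    heteroscedastic) or the Wilcoxon rank-sum (Mann–Whitney) test.
    """
    sub = table[(table["dataset_label"] == dataset_label) & (table["layer"] == layer)]
    ctl = sub.loc[sub["group"] == "control", metric].to_numpy()
    eae = sub.loc[sub["group"] == "EAE", metric].to_numpy()
    if len(ctl) < 3 or len(eae) < 3:
        raise ValueError("need at least 3 animals per group")
    if np.ptp(np.concatenate([ctl, eae])) == 0:
        return TestResult("t-test", 0.0, 1.0, comparison=f"{metric}@{dataset_label}/{layer}")
    normal = stats.shapiro(ctl)[1] >= alpha and stats.shapiro(eae)[1] >= alpha
    if normal:
        equal_var = stats.levene(ctl, eae)[1] >= alpha
        stat, p = stats.ttest_ind(ctl, eae, equal_var=equal_var)
        method = "t-test" if equal_var else "Welch t-test"
    else:
        stat, p = stats.mannwhitneyu(ctl, eae, alternative="two-sided")
        method = "Wilcoxon rank-sum"
    return TestResult(
        method, float(stat), float(p), comparison=f"{metric}@{dataset_label}/{layer}"
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    n = len(dist)
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        # gain of adding each candidate: total reduction in nearest-medoid cost
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def pam_cluster(
    feature_rows: np.ndarray | pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    truth=None,
    standardize: bool = False,
) -> ClusterResult:
    """Partition Around Medoids with Euclidean distance (BUILD + SWAP).

    Deterministic: BUILD greedily seeds the medoids, SWAP applies the best
    improving (medoid, candidate) exchange until none improves, ties broken
    by lowest index; ``seed`` is accepted for interface uniformity but the
    algorithm involves no randomness.  If ``truth`` labels are given, the
    adjusted Rand index and the misclassification count after optimal
    cluster-to-class matching are attached to the result.
    """
    X = np.asarray(feature_rows, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature_rows must be 2D")
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    medoids = _pam_build(dist, k)
    cost = float(dist[:, medoids].min(axis=1).sum())
    history = [cost]
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                new_cost = float(dist[:, trial].min(axis=1).sum())
                delta = new_cost - cost
                if delta < best[0] - 1e-15:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            history.append(cost)
            improved = True
    medoids = sorted(medoids)
    assignments = np.argmin(dist[:, medoids], axis=1)
    result = ClusterResult(assignments, np.array(medoids), cost, history)
    if truth is not None:
        truth = np.asarray(truth)
        result.ari = adjusted_rand_index(assignments, truth)
        result.n_misclassified = misclassification_count(assignments, truth)
    return result


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand agreement between two partitions, in [−1, 1]."""
    return float(adjusted_rand_score(labels_a, labels_b))


def misclassification_count(assignments, truth) -> int:
    """Items outside the maximum-agreement (Hungarian) cluster↔class matching."""
    assignments = np.asarray(assignments)
    truth = np.asarray(truth)
    cl = np.unique(assignments)
    tl = np.unique(truth)
    cont = np.zeros((len(cl), len(tl)), dtype=int)
    for i, c in enumerate(cl):
        for j, t in enumerate(tl):
            cont[i, j] = int(np.count_nonzero((assignments == c) & (truth == t)))
    ri, ci = linear_sum_assignment(-cont)
    return int(len(truth) - cont[ri, ci].sum())


# ---------------------------------------------------------------------------
# End-to-end analysis
# ---------------------------------------------------------------------------


def _fit_all(
    cohort: list[DWIDataset], options: AnalysisOptions
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Reconstruct datasets, fit DTI (and optionally DKI), extract VOI rows."""
    from .models import DiffusionKurtosisModel, DiffusionTensorModel
    from .qc import quality_report

    voi_frames, qc_rows = [], []
    labelmap = cohort[0].labelmap
    masks = standard_dataset_masks(cohort[0].scheme)  # same scheme cohort-wide
    for ds in cohort:
        for label, vmask in masks.items():
            sub = ds.subset(vmask, label)
            res = DiffusionTensorModel.from_dataset(sub).fit()
            maps = res.metric_maps()
            df = voi_means_from_maps(maps, sub.labelmap)
            df.insert(0, "animal_id", ds.animal_id)
            df.insert(1, "group", ds.group)
            df.insert(2, "dataset_label", label)
            voi_frames.append(df)
            rep = quality_report(sub, maps["SSE"], label)
            qc_rows.append(
                {
                    "animal_id": ds.animal_id,
                    "group": ds.group,
                    "dataset_label": label,
                    "snr_b0": rep.snr_b0,
                    "snr_global": rep.snr_global,
                    **{f"cnr_{k}": v for k, v in rep.cnr_per_voi.items()},
                    **{f"sse_{k}": v for k, v in rep.sse_per_voi.items()},
                }
            )
        if options.fit_dki:
            dki = DiffusionKurtosisModel.from_dataset(ds).fit()
            df = voi_means_from_maps(dki.metric_maps(), ds.labelmap)
            df.insert(0, "animal_id", ds.animal_id)
            df.insert(1, "group", ds.group)
            df.insert(2, "dataset_label", "DKI-2shell")
            voi_frames.append(df)
    return pd.concat(voi_frames, ignore_index=True), pd.DataFrame(qc_rows), labelmap


def run_full_analysis(
    cohort: list[DWIDataset],
    options: AnalysisOptions = AnalysisOptions(),
    seed: int = 0,
) -> dict:
    """Full pipeline on a simulated/loaded cohort.

    Returns a bundle of DataFrames: ``voi_table``, ``qc_table``,
    ``layer_tests`` (control animals), ``clustering`` (per-dataset PAM + ARI
    on control VOIs) and ``eae_tests`` (if both groups are present).
    """
    voi, qc_table, _ = _fit_all(cohort, options)
    ctl = voi[(voi["group"] == "control") & voi["layer"].isin(GM_LAYERS)]
    dlabels = [d for d in DATASET_LABELS if d in set(voi["dataset_label"])]

    layer_rows = []
    for dlabel in dlabels:
        for metric in DTI_METRICS:
            try:
                omnibus, posthoc = compare_layers(ctl, metric, dlabel, alpha=options.alpha)
            except ValueError:
                continue
            layer_rows.append(omnibus.as_dict())
            layer_rows.extend(t.as_dict() for t in posthoc)

    cluster_rows = []
    for dlabel in dlabels:
        sub = ctl[ctl["dataset_label"] == dlabel].sort_values(["animal_id", "layer"])
        feats = sub[list(options.features)].to_numpy()
        truth = sub["layer"].to_numpy()
        res = pam_cluster(feats, k=3, seed=seed, truth=truth, standardize=options.standardize)
        # is ML isolated in a pure cluster?
        ml_ids = set(res.assignments[truth == "ML"])
        ml_pure = len(ml_ids) == 1 and set(
            truth[res.assignments == next(iter(ml_ids))]
        ) == {"ML"}
        cluster_rows.append(
            {
                "dataset_label": dlabel,
                "ari": res.ari,
                "n_misclassified": res.n_misclassified,
                "ml_pure_cluster": bool(ml_pure),
            }
        )

    eae_rows = []
    n_per_group = voi.groupby("group")["animal_id"].nunique()
    if n_per_group.get("EAE", 0) >= 3 and n_per_group.get("control", 0) >= 3:
        for dlabel in dlabels:
            for metric in DTI_METRICS:
                t = eae_compare(voi, metric, dlabel, layer="ML", alpha=options.alpha)
                eae_rows.append(t.as_dict())
        if options.fit_dki and "DKI-2shell" in set(voi["dataset_label"]):
            for metric in ("D_mean", "D_ax", "D_rad", "K_mean", "K_ax", "K_rad", "MKT", "KFA", "dki_FA"):
                t = eae_compare(voi, metric, "DKI-2shell", layer="ML", alpha=options.alpha)
                eae_rows.append(t.as_dict())

    return {
        "voi_table": voi,
        "qc_table": qc_table,
        "layer_tests": pd.DataFrame(layer_rows),
        "clustering": pd.DataFrame(cluster_rows),
        "eae_tests": pd.DataFrame(eae_rows),
    }
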