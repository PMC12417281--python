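"""The validation battery: SSIM, NRMSE, ICC, Bland-Altman, AUROC/DeLong.

Conventions:

* SSIM uses a Gaussian window (sigma 1.5, 11 wide) and is averaged within a
  mask; the data range defaults to the ground-truth robust maximum (99.5th
  percentile).
* NRMSE is RMSE over the mask divided by the ground-truth range within the
  mask, reported in percent.
* ICC is the two-way random-effects, absolute-agreement, single-measurement
  coefficient ICC(A,1) (interchangeable "raters": AIF selections for the
  conventional pathway, prediction samples for the network pathway).
* AUROC is the Mann-Whitney statistic (ties at half weight); variance, CIs
  and the paired two-sided test follow DeLong's structural components.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.stats import norm
from skimage.metrics import structural_similarity

from dcepk.physics import PKMaps

__all__ = [
    "ssim_map",
    "nrmse",
    "icc",
    "bland_altman",
    "roc_auc",
    "delong_paired_test",
    "subject_score",
    "evaluate_cohort",
    "ReliabilityReport",
]

log = logging.getLogger(__name__)

PARAMS = ("ktrans", "ve", "vp")


# ---------------------------------------------------------------------------
# map-level similarity
# ---------------------------------------------------------------------------

def ssim_map(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
             data_range: float | None = None) -> float:
    """Mean SSIM of ``b`` against reference ``a`` within ``mask``.

    3-D inputs are scored per z-slice with a 2-D 11x11 Gaussian window
    (sigma 1.5) and pooled over masked voxels.  ``data_range`` defaults to the
    99.5th percentile of ``a`` within the mask.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps are not aligned")
    if a.ndim == 2:
        a, b = a[..., None], b[..., None]
    mask = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if data_range is None:
        data_range = float(np.percentile(a[mask], 99.5)) if mask.any() else 0.0
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    vals, weights = [], []
    for z in range(a.shape[2]):
        mz = mask[:, :, z]
        if not mz.any():
            continue
        _, smap = structural_similarity(
            a[:, :, z], b[:, :, z], data_range=data_range,
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            full=True,
        )
        vals.append(smap[mz].sum())
        weights.append(mz.sum())
    return float(np.sum(vals) / np.sum(weights))


def nrmse(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error of ``b`` vs ground truth ``a`` over ``mask``,
    normalised by the ground-truth range within the mask, in percent."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps are not aligned")
    mask = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ga, gb = a[mask], b[mask]
    rng = ga.max() - ga.min()
    if rng <= 0:
        raise ValueError("ground-truth range is zero within the mask")
    return float(np.sqrt(np.mean((ga - gb) ** 2)) / rng * 100.0)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def icc(measurements: np.ndarray, confidence: float = 0.95):
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is (subjects x raters) with no missing cells.  Returns
    ``(estimate, (lo, hi), flagged)`` where ``flagged`` is True when the
    between-subject variance vanishes (the coefficient is then undefined).
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    flagged = bool(np.isclose(m.mean(axis=1).var(), 0.0))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # degenerate inputs (perfect agreement) hit 0/0 in the F-based CI
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = res[res["Type"] == "ICC(A,1)"].iloc[0]
    est = float(row["ICC"])
    lo, hi = row["CI95"]
    if not (np.isfinite(lo) and np.isfinite(hi)):
        lo = hi = est  # perfect agreement: the interval collapses
    return est, (float(lo), float(hi)), flagged


def bland_altman(x: np.ndarray, y: np.ndarray):
    """Mean difference and 95% limits of agreement d_bar +/- 1.96 sd(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return mean_diff, (mean_diff - half, mean_diff + half)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    allr = _midranks(np.concatenate([pos, neg]))
    rp = _midranks(pos)
    rn = _midranks(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    return auc, v10, v01


def roc_auc(scores, labels, confidence: float = 0.95):
    """AUROC (Mann-Whitney, ties half-weighted) with a DeLong Wald CI.

    ``labels`` may be 0/1 or any two sortable values (the larger is taken as
    positive).  Returns ``(auc, (lo, hi))``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _binarize(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    var = _safe_var(v10) / len(v10) + _safe_var(v01) / len(v01)
    z = norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def delong_paired_test(scores_a, scores_b, labels):
    """Paired DeLong z-test for the difference of two correlated AUROCs.

    Both score vectors are computed on the same subjects.  Returns
    ``(delta_auc, z, p)``; identical score vectors give delta 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired scores must have the same subjects")
    labels = _binarize(labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)

    def paired_var(a, b, size):
        if size < 2:
            return 0.0
        s = np.cov(np.stack([a, b]), ddof=1)
        return (s[0, 0] + s[1, 1] - 2 * s[0, 1]) / size

    var = paired_var(v10_a, v10_b, m) + paired_var(v01_a, v01_b, n)
    delta = auc_a - auc_b
    if var <= 1e-16:
        return float(delta), 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return float(delta), float(z), float(p)


def _safe_var(v: np.ndarray) -> float:
    return float(v.var(ddof=1)) if len(v) >= 2 else 0.0


def _binarize(labels) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    return (labels == uniq[1]).astype(int)


# ---------------------------------------------------------------------------
# cohort-level assembly
# ---------------------------------------------------------------------------

def subject_score(maps: PKMaps, mask: np.ndarray) -> dict:
    """Per-parameter mean within the enhancing-tumor mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty enhancing mask")
    return {k: float(maps[k][mask].mean()) for k in PARAMS}


@dataclass
class ReliabilityReport:
    """All evaluation outputs for one test cohort."""

    ssim: dict = field(default_factory=dict)        # pathway -> param -> {total, tumor}
    nrmse: dict = field(default_factory=dict)       # pathway -> param -> {total, tumor}
    icc: dict = field(default_factory=dict)         # pathway -> param -> {icc, ci, flagged}
    bland_altman: dict = field(default_factory=dict)  # pathway -> param -> {mean_diff, loa}
    auroc: dict = field(default_factory=dict)       # task -> pathway -> param -> {auc, ci}
    delong: dict = field(default_factory=dict)      # task -> param -> {delta, z, p}
    ablation: dict = field(default_factory=dict)    # param -> {ssim_full, ssim_tcn_only, ...}
    subject_scores: dict = field(default_factory=dict)  # pathway -> param -> [[per rater/sample]]
    labels: dict = field(default_factory=dict)      # task -> 0/1 list
    n_test: int = 0
    excluded: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def tables(self) -> dict:
        """Human-readable DataFrames (one per block)."""
        rows = []
        for pathway, per in self.ssim.items():
            for p, v in per.items():
                rows.append({"pathway": pathway, "param": p, "metric": "ssim_total", "value": v["total"]})
        for pathway, per in self.nrmse.items():
            for p, v in per.items():
                rows.append({"pathway": pathway, "param": p, "metric": "nrmse_total", "value": v["total"]})
                rows.append({"pathway": pathway, "param": p, "metric": "nrmse_tumor", "value": v["tumor"]})
        return {"similarity": pd.DataFrame(rows)}


def plot_report(report: "ReliabilityReport", scores: dict, labels: dict, out_dir) -> list:
    """Bland-Altman and ROC figures for a report; returns written paths.

    ``scores``: pathway -> param -> (n_subjects, n_raters) arrays;
    ``labels``: task -> 0/1 vector.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(len(scores), 3, figsize=(11, 3.2 * len(scores)), squeeze=False)
    for r, (pathway, per) in enumerate(scores.items()):
        for c, p in enumerate(PARAMS):
            m = np.asarray(per[p])
            x, y = m[:, 0], m[:, 1]
            md, loa = bland_altman(x, y)
            ax = axes[r][c]
            ax.scatter((x + y) / 2, x - y, s=12)
            for v, style in ((md, "-"), (loa[0], "--"), (loa[1], "--")):
                ax.axhline(v, ls=style, c="gray", lw=0.8)
            ax.set_title(f"{pathway} {p}")
            ax.set_xlabel("mean of raters")
            ax.set_ylabel("difference")
    fig.tight_layout()
    ba_path = out_dir / "bland_altman.png"
    fig.savefig(ba_path, dpi=110)
    plt.close(fig)
    written.append(ba_path)

    fig, axes = plt.subplots(1, len(labels), figsize=(5 * len(labels), 4), squeeze=False)
    for c, (task, lab) in enumerate(labels.items()):
        ax = axes[0][c]
        for pathway, per in scores.items():
            for p in PARAMS:
                sc = np.asarray(per[p]).mean(axis=1)
                order = np.argsort(-sc)
                tpr = np.concatenate([[0], np.cumsum(lab[order]) / max(lab.sum(), 1)])
                fpr = np.concatenate([[0], np.cumsum(1 - lab[order]) / max((1 - lab).sum(), 1)])
                ax.plot(fpr, tpr, lw=1, label=f"{pathway} {p}")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(f"ROC: {task}")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
    fig.tight_layout()
    roc_path = out_dir / "roc.png"
    fig.savefig(roc_path, dpi=110)
    plt.close(fig)
    written.append(roc_path)
    return written


def evaluate_cohort(
    subjects: list,
    conventional: dict,
    predictions: dict,
    tcn_only_maps: dict | None = None,
    data_ranges: dict | None = None,
) -> ReliabilityReport:
    """Assemble the full reliability/diagnostic report on a test cohort.

    Parameters
    ----------
    subjects : list of SyntheticSubject (test split; supply gt maps, masks,
        labels).
    conventional : subject_id -> list of PKMaps, one per AIF rater (>= 2).
    predictions : subject_id -> PredictionSet (>= 2 samples).
    tcn_only_maps : optional subject_id -> PKMaps from the ablation model.
    data_ranges : optional per-parameter SSIM data range; defaults to the
        cohort ground-truth 99.5th percentile.
    """
    report = ReliabilityReport()
    missing = [s.subject_id for s in subjects
               if s.subject_id not in conventional or s.subject_id not in predictions]
    if missing:
        raise ValueError(f"missing pathway outputs for subjects: {missing}")
    usable = []
    for s in subjects:
        if s.masks["enhancing_tumor"].any():
            usable.append(s)
        else:
            report.excluded.append(s.subject_id)
            log.info("excluding %s: empty enhancing mask", s.subject_id)
    report.n_test = len(usable)

    if data_ranges is None:
        data_ranges = {
            p: float(np.percentile(np.concatenate([s.gt_maps[p].ravel() for s in usable]), 99.5))
            for p in PARAMS
        }

    # --- similarity of the network mean maps (and ablation) to ground truth
    for pathway, maps_of in (
        ("synthetic", {s.subject_id: predictions[s.subject_id].mean_maps for s in usable}),
        ("tcn_only", tcn_only_maps or {}),
    ):
        if not maps_of:
            continue
        report.ssim[pathway] = {}
        report.nrmse[pathway] = {}
        for p in PARAMS:
            stot = [ssim_map(s.gt_maps[p], maps_of[s.subject_id][p], s.masks["brain"], data_ranges[p])
                    for s in usable]
            stum = [ssim_map(s.gt_maps[p], maps_of[s.subject_id][p], s.masks["whole_tumor"], data_ranges[p])
                    for s in usable]
            ntot = [nrmse(s.gt_maps[p], maps_of[s.subject_id][p], s.masks["brain"]) for s in usable]
            ntum = [nrmse(s.gt_maps[p], maps_of[s.subject_id][p], s.masks["whole_tumor"]) for s in usable]
            report.ssim[pathway][p] = {"total": float(np.mean(stot)), "tumor": float(np.mean(stum))}
            report.nrmse[pathway][p] = {"total": float(np.mean(ntot)), "tumor": float(np.mean(ntum))}
    if tcn_only_maps:
        for p in PARAMS:
            report.ablation[p] = {
                "ssim_full": report.ssim["synthetic"][p]["total"],
                "ssim_tcn_only": report.ssim["tcn_only"][p]["total"],
                "nrmse_full": report.nrmse["synthetic"][p]["total"],
                "nrmse_tcn_only": report.nrmse["tcn_only"][p]["total"],
            }

    # --- subject-level scores per rater / per sample
    conv_scores = {p: [] for p in PARAMS}  # per param: (n_subj, n_raters)
    pred_scores = {p: [] for p in PARAMS}
    for s in usable:
        emask = s.masks["enhancing_tumor"]
        raters = conventional[s.subject_id]
        if len(raters) < 2:
            raise ValueError("need >= 2 conventional raters")
        for p in PARAMS:
            conv_scores[p].append([subject_score(m, emask)[p] for m in raters])
        ps = predictions[s.subject_id]
        e2d = emask[..., 0]  # samples are (3, H, W); masks carry a z axis
        for p in PARAMS:
            pi = PARAMS.index(p)
            pred_scores[p].append([float(samp[pi][e2d].mean()) for samp in ps.samples])

    report.subject_scores = {
        "conventional": {p: [list(map(float, r)) for r in conv_scores[p]] for p in PARAMS},
        "synthetic": {p: [list(map(float, r)) for r in pred_scores[p]] for p in PARAMS},
    }
    report.icc = {"conventional": {}, "synthetic": {}}
    report.bland_altman = {"conventional": {}, "synthetic": {}}
    for p in PARAMS:
        cm = np.asarray(conv_scores[p])
        pm = np.asarray(pred_scores[p])
        for pathway, m in (("conventional", cm), ("synthetic", pm)):
            est, ci, flagged = icc(m)
            report.icc[pathway][p] = {"icc": est, "ci": list(ci), "flagged": flagged}
            md, loa = bland_altman(m[:, 0], m[:, 1])
            report.bland_altman[pathway][p] = {"mean_diff": md, "loa": list(loa)}

    # --- diagnostic AUROC per task, pathway, parameter
    tasks = {
        "grade": np.array([1 if s.label_grade == "high" else 0 for s in usable]),
        "idh": np.array([1 if s.label_idh == "wildtype" else 0 for s in usable]),
    }
    report.labels = {t: [int(v) for v in lab] for t, lab in tasks.items()}
    for task, labels in tasks.items():
        if len(np.unique(labels)) < 2:
            log.warning("task %s has a single class in the test split; skipped", task)
            continue
        report.auroc[task] = {"conventional": {}, "synthetic": {}}
        report.delong[task] = {}
        for p in PARAMS:
            conv_mean = np.asarray(conv_scores[p]).mean(axis=1)
            pred_mean = np.asarray(pred_scores[p]).mean(axis=1)
            for pathway, sc in (("conventional", conv_mean), ("synthetic", pred_mean)):
                auc, ci = roc_auc(sc, labels)
                report.auroc[task][pathway][p] = {"auc": auc, "ci": list(ci)}
            delta, z, pval = delong_paired_test(pred_mean, conv_mean, labels)
            report.delong[task][p] = {"delta": delta, "z": z, "p": pval}
    return report
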