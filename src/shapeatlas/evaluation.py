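"""Goodness measures, optimal-threshold selection, the leave-one-out
experiment over atlas x registration combinations, and paired testing.

Measures: Dice 2V(A&B)/(V(A)+V(B)); Jaccard V(A&B)/V(A|B); Hausdorff as the
max directed sup-inf voxel-center distance in mm; IProb = mean atlas
probability inside the target shape minus the mean outside it (over the
full window), in [-1, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .coverage import ncf_atlas
from .errors import DomainError, PairingError, UndefinedMeasureError
from .glm import GLMConfig, glm_atlas
from .registration import (
    Model,
    RegistrationOptions,
    apply_params,
    coregister_sample,
    register,
    register_demons,
)
from .statistical import StatAtlasConfig, statistical_atlas
from .volumes import BinaryVolume, ProbabilityVolume, assert_common_frame, threshold_atlas

__all__ = [
    "ATLAS_METHODS",
    "REGISTRATION_MODELS",
    "EvalRecord",
    "ComparisonTable",
    "dice",
    "jaccard",
    "hausdorff",
    "iprob",
    "best_threshold_eval",
    "leave_one_out",
    "compare_methods",
    "method_label",
    "DEFAULT_THRESHOLDS",
]

ATLAS_METHODS = ("NCF", "GLM", "STA")
REGISTRATION_MODELS = {"rigid": "R", "similarity": "TRS", "affine": "A", "demons": "D"}
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10))


def method_label(atlas_method: str, reg_model: str) -> str:
    return f"{atlas_method}+{REGISTRATION_MODELS.get(reg_model, reg_model)}"


# ---------------------------------------------------------------------------
# Binary-shape measures
# ---------------------------------------------------------------------------


def _counts(a: BinaryVolume, b: BinaryVolume):
    assert_common_frame([a, b])
    av = a.occupancy.astype(bool)
    bv = b.occupancy.astype(bool)
    return int(np.count_nonzero(av & bv)), int(np.count_nonzero(av)), int(
        np.count_nonzero(bv)
    )


def dice(a: BinaryVolume, b: BinaryVolume) -> float:
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        raise UndefinedMeasureError("Dice undefined for two empty shapes")
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryVolume, b: BinaryVolume) -> float:
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        raise UndefinedMeasureError("Jaccard undefined for two empty shapes")
    return inter / union


def hausdorff(a: BinaryVolume, b: BinaryVolume) -> float:
    """Symmetric Hausdorff distance (mm) between the voxel-center sets."""
    assert_common_frame([a, b])
    if a.empty or b.empty:
        raise UndefinedMeasureError("Hausdorff undefined for an empty shape")
    sampling = a.grid.spacing
    av = a.occupancy.astype(bool)
    bv = b.occupancy.astype(bool)
    dist_to_b = ndimage.distance_transform_edt(~bv, sampling=sampling)
    dist_to_a = ndimage.distance_transform_edt(~av, sampling=sampling)
    return float(max(dist_to_b[av].max(), dist_to_a[bv].max()))


def iprob(p: ProbabilityVolume, s: BinaryVolume) -> float:
    """Mean probability inside S minus mean probability outside (window W)."""
    assert_common_frame([p, s])
    sv = s.occupancy.astype(bool)
    n_in = int(np.count_nonzero(sv))
    n_out = sv.size - n_in
    if n_in == 0 or n_out == 0:
        raise UndefinedMeasureError("IProb needs 0 < V(S) < V(W)")
    prob = p.prob.astype(np.float64)
    return float(prob[sv].mean() - prob[~sv].mean())


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def best_threshold_eval(
    p: ProbabilityVolume,
    truth: BinaryVolume,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict:
    """Best Dice/Jaccard (max) and Hausdorff (min) over a threshold sweep.

    Thresholds whose binarization leaves a measure undefined are skipped for
    that measure; ties resolve to the lowest threshold.
    """
    best = {
        "dice": (-np.inf, None),
        "jaccard": (-np.inf, None),
        "hausdorff": (np.inf, None),
    }
    for t in thresholds:
        shape = threshold_atlas(p, t)
        for name, func, better in (
            ("dice", dice, lambda new, old: new > old + 1e-15),
            ("jaccard", jaccard, lambda new, old: new > old + 1e-15),
            ("hausdorff", hausdorff, lambda new, old: new < old - 1e-15),
        ):
            try:
                val = func(shape, truth)
            except UndefinedMeasureError:
                continue
            if better(val, best[name][0]):
                best[name] = (val, float(t))
    if any(v[1] is None for v in best.values()):
        raise UndefinedMeasureError("every threshold left a measure undefined")
    return {
        "dice": best["dice"][0],
        "jaccard": best["jaccard"][0],
        "hausdorff": best["hausdorff"][0],
        "thresholds": {k: best[k][1] for k in best},
    }


# ---------------------------------------------------------------------------
# Leave-one-out harness
# ---------------------------------------------------------------------------


@dataclass
class EvalRecord:
    case_id: str
    method: str                  # e.g. "GLM+TRS"
    dice: float
    jaccard: float
    hausdorff: float
    iprob: float | None = None   # absent for the binary STA atlas
    threshold_used: float | None = None

    def __post_init__(self):
        if self.jaccard > self.dice + 1e-9:
            raise DomainError("jaccard cannot exceed dice")


@dataclass
class LeaveOneOutConfig:
    reg_opts: RegistrationOptions = field(default_factory=RegistrationOptions)
    glm: GLMConfig = field(default_factory=GLMConfig)
    sta: StatAtlasConfig = field(default_factory=StatAtlasConfig)
    thresholds: tuple = DEFAULT_THRESHOLDS
    reference: int | None = None  # fixed reference index; None = auto-select


def _register_heldout(truth: BinaryVolume, reference: BinaryVolume,
                      reg_model: Model, opts: RegistrationOptions) -> BinaryVolume:
    if reg_model == "demons":
        fld, _ = register_demons(truth, reference, opts)
        return apply_params(truth, fld)
    res = register(truth, reference, reg_model, opts)
    return apply_params(truth, res.params)


def _build_atlas(aligned, atlas_method: str, cfg: LeaveOneOutConfig):
    if atlas_method == "NCF":
        return ncf_atlas(aligned)
    if atlas_method == "GLM":
        return glm_atlas(aligned, cfg.glm)
    if atlas_method == "STA":
        return statistical_atlas(aligned, cfg.sta)[0]
    raise DomainError(f"unknown atlas method {atlas_method!r}")


def evaluate_atlas(atlas, truth: BinaryVolume, atlas_method: str, case_id: str,
                   reg_model: str, thresholds=DEFAULT_THRESHOLDS) -> EvalRecord:
    """Score one atlas against one ground-truth shape."""
    label = method_label(atlas_method, reg_model)
    if atlas_method == "STA":
        return EvalRecord(
            case_id, label,
            dice(atlas, truth), jaccard(atlas, truth), hausdorff(atlas, truth),
        )
    best = best_threshold_eval(atlas, truth, thresholds)
    return EvalRecord(
        case_id, label, best["dice"], best["jaccard"], best["hausdorff"],
        iprob=iprob(atlas, truth), threshold_used=best["thresholds"]["dice"],
    )


def leave_one_out(
    sample: Sequence[tuple[str, BinaryVolume]],
    atlas_method: str,
    reg_model: Model,
    cfg: LeaveOneOutConfig | None = None,
) -> list[EvalRecord]:
    """One EvalRecord per exploration, holding the whole patient out.

    ``sample`` pairs each binary shape with its patient id; explorations of
    the held-out patient never enter the atlas.  The held-out ground truth
    is registered into the atlas frame with the same geometric model.
    """
    cfg = cfg or LeaveOneOutConfig()
    patients = [pid for pid, _ in sample]
    if len(set(patients)) < 3:
        raise DomainError("leave-one-out needs at least three patients")
    records: list[EvalRecord] = []
    for e, (pid, truth) in enumerate(sample):
        train = [vol for qid, vol in sample if qid != pid]
        aligned, ref_idx, _ = coregister_sample(
            train, reg_model, cfg.reg_opts, reference=cfg.reference
        )
        truth_in_frame = _register_heldout(
            truth, aligned[ref_idx], reg_model, cfg.reg_opts
        )
        atlas = _build_atlas(aligned, atlas_method, cfg)
        records.append(
            evaluate_atlas(
                atlas, truth_in_frame, atlas_method, f"case{e}:{pid}", reg_model,
                cfg.thresholds,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Paired comparison across methods
# ---------------------------------------------------------------------------

_MEASURES = ("dice", "jaccard", "hausdorff", "iprob")
_HIGHER_IS_BETTER = {"dice": True, "jaccard": True, "hausdorff": False, "iprob": True}


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    diff = x - y
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        # near-identical samples trip scipy's catastrophic-cancellation warning
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonTable:
    summary: pd.DataFrame                  # mean/sd per method x measure
    pvalues: dict[str, pd.DataFrame]       # per measure, symmetric, NaN diag
    significant: dict[str, pd.DataFrame]   # adjusted p < alpha flags
    winners: dict[str, pd.DataFrame]       # label of the better method
    n_tests: int
    alpha: float = 0.05


def compare_methods(
    records: Sequence[EvalRecord],
    alpha: float = 0.05,
    adjust: str = "holm",
) -> ComparisonTable:
    """Per-method mean +/- sd and all-pairs paired two-sided t tests.

    p-values are multiplicity-adjusted per measure (Holm by default;
    ``bonferroni`` and ``none`` are available).
    """
    if adjust not in ("holm", "bonferroni", "none"):
        raise DomainError(f"unknown adjustment {adjust!r}")
    by_method: dict[str, dict[str, dict[str, float]]] = {}
    for r in records:
        per_case = by_method.setdefault(r.method, {})
        per_case[r.case_id] = {
            "dice": r.dice, "jaccard": r.jaccard, "hausdorff": r.hausdorff,
            "iprob": r.iprob,
        }
    methods = sorted(by_method)
    if len(methods) < 2:
        raise DomainError("compare_methods needs at least two methods")
    case_sets = {m: set(by_method[m]) for m in methods}
    cases = sorted(case_sets[methods[0]])
    for m in methods:
        if case_sets[m] != set(cases):
            raise PairingError(f"method {m} evaluated on a different case set")
    if len(cases) < 2:
        raise DomainError("need at least two paired cases per method")

    rows = []
    for m in methods:
        row = {"method": m}
        for meas in _MEASURES:
            vals = [by_method[m][c][meas] for c in cases]
            if any(v is None for v in vals):
                row[f"{meas}_mean"] = np.nan
                row[f"{meas}_sd"] = np.nan
            else:
                row[f"{meas}_mean"] = float(np.mean(vals))
                row[f"{meas}_sd"] = float(np.std(vals, ddof=1))
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("method")

    pmats, sigmats, winmats = {}, {}, {}
    n_tests = 0
    pairs = list(itertools.combinations(methods, 2))
    for meas in _MEASURES:
        have = [
            m for m in methods
            if all(by_method[m][c][meas] is not None for c in cases)
        ]
        pmat = pd.DataFrame(np.nan, index=methods, columns=methods)
        winmat = pd.DataFrame("", index=methods, columns=methods)
        raw = []
        tested = []
        for a, b in pairs:
            if a not in have or b not in have:
                continue
            xa = np.array([by_method[a][c][meas] for c in cases], dtype=float)
            xb = np.array([by_method[b][c][meas] for c in cases], dtype=float)
            _, pv = _paired_t(xa, xb)
            raw.append(pv)
            better = a if (
                (xa.mean() > xb.mean()) == _HIGHER_IS_BETTER[meas]
                and xa.mean() != xb.mean()
            ) else (b if xa.mean() != xb.mean() else "")
            tested.append((a, b, better))
        if meas == "dice":
            n_tests = len(tested)
        if adjust == "holm":
            adj = holm_adjust(raw) if raw else np.array([])
        elif adjust == "bonferroni":
            adj = np.minimum(np.asarray(raw) * len(raw), 1.0) if raw else np.array([])
        else:
            adj = np.asarray(raw)
        for (a, b, better), pv in zip(tested, adj):
            pmat.loc[a, b] = pmat.loc[b, a] = pv
            winmat.loc[a, b] = winmat.loc[b, a] = better
        pmats[meas] = pmat
        sigmats[meas] = pmat < alpha
        winmats[meas] = winmat

    return ComparisonTable(summary, pmats, sigmats, winmats, n_tests, alpha)
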