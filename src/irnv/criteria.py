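"""Decision-tree split criteria over precise and credal class estimates.

Three criteria are implemented for ranking categorical predictors of a
discrete class:

* **IGR** — the classic C4.5 info-gain ratio: Shannon info-gain of the class
  given the predictor, normalised by the predictor's own entropy.
* **IIG** — imprecise info-gain: the class distribution at a node is replaced
  by the credal set of the imprecise Dirichlet model (IDM), per-class
  intervals ``[n_i/(N+s), (n_i+s)/(N+s)]`` with hyperparameter ``s`` (default
  1), and entropy is replaced by the *maximum* entropy H* over that set.
  Unlike info-gain, IIG can be negative: it penalises predictors that worsen
  the information on the class.
* **A-NPIM** — same construction with the parameter-free approximate
  nonparametric predictive inference intervals
  ``[max(0,(n_i-1)/N), min((n_i+1)/N, 1)]``.

All entropies are in bits.  Class counts may be real-valued: fractional
weights arise from C4.5-style missing-value splitting.  When a predictor has
missing values, a criterion is evaluated on the observed weight only and the
gain is scaled by the observed-weight fraction (the C4.5 convention).

H* over a box of probability intervals intersected with the simplex has the
water-filling form ``p_i = clamp(lam, l_i, u_i)`` with the common level
``lam`` chosen so the probabilities sum to one; :func:`max_entropy_distribution`
solves this by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import AccidentDataset, FATAL, SLIGHT

__all__ = [
    "WeightedClassCounts",
    "ProbabilityIntervals",
    "CriterionScore",
    "shannon_entropy",
    "variable_entropy",
    "conditional_entropy",
    "info_gain",
    "info_gain_ratio",
    "idm_intervals",
    "anpim_intervals",
    "max_entropy_distribution",
    "max_entropy_binary",
    "imprecise_gain",
]

_EPS = 1e-9


@dataclass(frozen=True)
class WeightedClassCounts:
    """Non-negative real per-class counts ``n_ci`` with total ``N``."""

    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative class count in {self.counts}")

    @property
    def total(self) -> float:
        return float(sum(self.counts))


@dataclass(frozen=True)
class ProbabilityIntervals:
    """Per-class ``[lower, upper]`` bounds defining a credal set.

    The credal set is ``{p : l_i <= p_i <= u_i, sum p_i = 1}``; it is
    non-empty iff ``sum(l) <= 1 <= sum(u)``.
    """

    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != up.shape:
            raise ValueError("lower/upper length mismatch")
        if (lo < -_EPS).any() or (up > 1 + _EPS).any() or (lo > up + _EPS).any():
            raise ValueError(f"invalid interval system {self.lower} / {self.upper}")

    @property
    def k(self) -> int:
        return len(self.lower)

    def is_feasible(self) -> bool:
        return sum(self.lower) <= 1 + _EPS and sum(self.upper) >= 1 - _EPS


@dataclass(frozen=True)
class CriterionScore:
    """A split-criterion evaluation; ``value`` is ``None`` when undefined."""

    criterion: str
    value: float | None
    s: float | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _plogp(p: np.ndarray) -> np.ndarray:
    """Elementwise ``-p * log2(p)`` with the ``0 log 0 = 0`` convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out


def shannon_entropy(distribution) -> float:
    """Shannon entropy in bits of a normalised probability vector."""
    p = np.asarray(distribution, dtype=float)
    if (p < -_EPS).any() or abs(p.sum() - 1.0) > _EPS:
        raise ValueError(f"not a probability distribution: {distribution}")
    return float(_plogp(np.clip(p, 0.0, 1.0)).sum())


def _observed_counts(dataset: AccidentDataset, variable: str):
    """Per-value, per-class observed weights for one predictor.

    Returns ``(values, branch_class_weights, w_obs, w_all)`` where
    ``branch_class_weights`` has one row per observed value and one column
    per class in ``(SLIGHT, FATAL)`` order.
    """
    if variable not in dataset.variable_names:
        raise KeyError(variable)
    col = dataset.frame[variable]
    obs = col.notna().to_numpy()
    w_all = float(dataset.weights.sum())
    if not obs.any():
        return np.array([], dtype=int), np.zeros((0, 2)), 0.0, w_all
    codes = col.to_numpy(dtype="float64", na_value=np.nan)[obs].astype(int)
    w = dataset.weights[obs]
    y = dataset.severity[obs]
    values = np.unique(codes)
    table = np.zeros((len(values), 2))
    for i, v in enumerate(values):
        sel = codes == v
        table[i, 0] = w[sel][y[sel] == SLIGHT].sum()
        table[i, 1] = w[sel][y[sel] == FATAL].sum()
    return values, table, float(w.sum()), w_all


def class_counts(dataset: AccidentDataset) -> WeightedClassCounts:
    y, w = dataset.severity, dataset.weights
    return WeightedClassCounts((float(w[y == SLIGHT].sum()), float(w[y == FATAL].sum())))


def variable_entropy(dataset: AccidentDataset, variable: str) -> float:
    """Entropy of a predictor over its observed weight."""
    _, table, w_obs, _ = _observed_counts(dataset, variable)
    if w_obs <= 0:
        raise ValueError(f"{variable}: no observed values")
    return float(_plogp(table.sum(axis=1) / w_obs).sum())


def conditional_entropy(dataset: AccidentDataset, variable: str) -> float:
    """Branch-weighted class entropy ``sum_i p(x_i) H_{D_i}(C)`` in bits."""
    _, table, w_obs, _ = _observed_counts(dataset, variable)
    if w_obs <= 0:
        raise ValueError(f"{variable}: no observed values")
    branch_tot = table.sum(axis=1)
    h = 0.0
    for row, tot in zip(table, branch_tot):
        if tot > 0:
            h += (tot / w_obs) * _plogp(row / tot).sum()
    return float(h)


def info_gain(dataset: AccidentDataset, variable: str) -> float:
    """C4.5 info-gain with the observed-fraction scaling for missing values."""
    _, table, w_obs, w_all = _observed_counts(dataset, variable)
    if w_obs <= 0:
        raise ValueError(f"{variable}: no observed values")
    marg = table.sum(axis=0)
    h_c = _plogp(marg / marg.sum()).sum()
    return float((w_obs / w_all) * (h_c - conditional_entropy(dataset, variable)))


def info_gain_ratio(dataset: AccidentDataset, variable: str) -> CriterionScore:
    """Info-gain normalised by the predictor's entropy; undefined for a
    constant predictor (the caller must skip the variable)."""
    _, table, w_obs, w_all = _observed_counts(dataset, variable)
    if w_obs <= 0:
        return CriterionScore("IGR", None)
    h_x = float(_plogp(table.sum(axis=1) / w_obs).sum())
    if h_x <= _EPS:
        return CriterionScore("IGR", None)
    return CriterionScore("IGR", info_gain(dataset, variable) / h_x)


def idm_intervals(counts: WeightedClassCounts, s: float = 1.0) -> ProbabilityIntervals:
    """IDM credal intervals ``[n_i/(N+s), (n_i+s)/(N+s)]``."""
    if s <= 0:
        raise ValueError("s must be positive")
    n = np.asarray(counts.counts, dtype=float)
    total = counts.total
    if total <= 0:
        raise ValueError("empty counts: intervals undefined")
    return ProbabilityIntervals(
        lower=tuple(n / (total + s)), upper=tuple((n + s) / (total + s))
    )


def anpim_intervals(counts: WeightedClassCounts) -> ProbabilityIntervals:
    """Parameter-free NPI intervals ``[max(0,(n_i-1)/N), min((n_i+1)/N, 1)]``."""
    n = np.asarray(counts.counts, dtype=float)
    total = counts.total
    if total <= 0:
        raise ValueError("empty counts: intervals undefined")
    return ProbabilityIntervals(
        lower=tuple(np.maximum(0.0, (n - 1) / total)),
        upper=tuple(np.minimum((n + 1) / total, 1.0)),
    )


def max_entropy_distribution(
    intervals: ProbabilityIntervals, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Argmax of Shannon entropy over a probability-interval credal set.

    The concave objective over the box-simplex intersection attains its
    maximum at the clamped common level ``p_i = clamp(lam, l_i, u_i)``; the
    level ``lam`` is found by bisection on the monotone sum constraint.
    Returns ``(p, H*)``.
    """
    lo = np.asarray(intervals.lower, dtype=float)
    up = np.asarray(intervals.upper, dtype=float)
    if not intervals.is_feasible():
        raise ValueError("empty credal set: sum(l) > 1 or sum(u) < 1")
    a, b = 0.0, 1.0
    while b - a > tol:
        lam = 0.5 * (a + b)
        if np.clip(lam, lo, up).sum() < 1.0:
            a = lam
        else:
            b = lam
    p = np.clip(0.5 * (a + b), lo, up)
    # absorb the residual bisection error without leaving the box
    resid = 1.0 - p.sum()
    if abs(resid) > 0:
        room = (up - p) if resid > 0 else (p - lo)
        total_room = room.sum()
        if total_room > 0:
            p = p + np.sign(resid) * room * min(abs(resid) / total_room, 1.0)
    return p, float(_plogp(p).sum())


def max_entropy_binary(
    n1: np.ndarray, n2: np.ndarray, model: str, s: float = 1.0
) -> np.ndarray:
    """Vectorised two-class H* for IDM (``model='idm'``) or NPI (``'npi'``).

    For two classes the credal set reduces to an interval for ``p_1`` and the
    entropy maximiser is the point of that interval closest to 1/2.  Used on
    per-branch count arrays inside the tree builder; agrees with
    :func:`max_entropy_distribution` (tested).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    total = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "idm":
            lo = n1 / (total + s)
            up = (n1 + s) / (total + s)
        elif model == "npi":
            lo = np.maximum(0.0, (n1 - 1) / total)
            up = np.minimum((n1 + 1) / total, 1.0)
        else:
            raise ValueError(f"unknown credal model {model!r}")
    p1 = np.clip(0.5, lo, up)
    h = _plogp(p1) + _plogp(1.0 - p1)
    return np.where(total > 0, h, 0.0)


def _model_intervals(counts: WeightedClassCounts, model: str, s: float):
    if model == "idm":
        return idm_intervals(counts, s)
    if model == "npi":
        return anpim_intervals(counts)
    raise ValueError(f"unknown credal model {model!r}")


def imprecise_gain(
    dataset: AccidentDataset, variable: str, model: str = "idm", s: float = 1.0
) -> CriterionScore:
    """IIG (``model='idm'``) or A-NPIM (``model='npi'``) of one predictor.

    ``H*(K(C)) - sum_i p(x_i) H*(K(C | X = x_i))`` with per-branch credal
    sets built from that branch's weighted class counts; may be negative.
    Scaled by the observed-weight fraction when the predictor has missing
    values.
    """
    name = "IIG" if model == "idm" else "ANPIM"
    _, table, w_obs, w_all = _observed_counts(dataset, variable)
    if w_obs <= 0:
        return CriterionScore(name, None, s if model == "idm" else None)
    marg = WeightedClassCounts(tuple(table.sum(axis=0)))
    _, h_marg = max_entropy_distribution(_model_intervals(marg, model, s))
    h_cond = 0.0
    for row in table:
        tot = row.sum()
        if tot > 0:
            _, h_b = max_entropy_distribution(
                _model_intervals(WeightedClassCounts(tuple(row)), model, s)
            )
            h_cond += (tot / w_obs) * h_b
    value = (w_obs / w_all) * (h_marg - h_cond)
    return CriterionScore(name, float(value), s if model == "idm" else None)
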