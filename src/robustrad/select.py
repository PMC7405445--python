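"""The thirteen feature-selection methods, implemented from first principles.

Four univariate filters (Fisher score, Gini impurity reduction, chi-square,
t-score), ReliefF, and the eight greedy forward selectors of the
conditional-likelihood-maximization mutual-information family (MIM, MIFS,
MRMR, JMI, CIFE, CMIM, ICAP, DISR).  Mutual information is the plug-in
estimate on equal-frequency-discretized features (default 5 bins), in bits.

Greedy step criteria, with S the already-selected set and f a candidate:

    MIM   I(f;y)
    MIFS  I(f;y) - beta * sum_s I(f;s)
    MRMR  I(f;y) - (1/|S|) sum_s I(f;s)
    JMI   sum_s I((f,s);y)
    CIFE  I(f;y) - sum_s [ I(f;s) - I(f;s|y) ]
    CMIM  min_s I(f;y|s)
    ICAP  I(f;y) - sum_s max(0, I(f;s) - I(f;s|y))
    DISR  sum_s I((f,s);y) / H(f,s)

Ties are broken by feature order.  Selection is always fit on training data
only; the benchmark harness passes nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SELECTOR_METHODS = (
    "RELF", "FSCR", "GINI", "CHSQ", "TSCR",
    "MIM", "MIFS", "MRMR", "JMI", "CIFE", "DISR", "CMIM", "ICAP",
)
MI_METHODS = ("MIM", "MIFS", "MRMR", "JMI", "CIFE", "DISR", "CMIM", "ICAP")
BINARY_ONLY = ("TSCR",)


@dataclass(frozen=True)
class SelectorSpec:
    method: str = "MRMR"
    k: int = 10
    discretization_bins: int = 5
    relieff_neighbors: int = 10
    mifs_beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SELECTOR_METHODS:
            raise ValueError(f"unknown selector {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


# --------------------------------------------------------------------------
# information-theoretic kernel
# --------------------------------------------------------------------------

def _encode(x: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(x, return_inverse=True)
    return codes, int(codes.max()) + 1


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(x: np.ndarray) -> float:
    codes, _ = _encode(np.asarray(x))
    return _entropy_from_counts(np.bincount(codes))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in I(x;y) in bits from the joint contingency table."""
    x, y = np.asarray(x), np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    cx, nx = _encode(x)
    cy, ny = _encode(y)
    joint = np.bincount(cx * ny + cy, minlength=nx * ny)
    hx = _entropy_from_counts(np.bincount(cx))
    hy = _entropy_from_counts(np.bincount(cy))
    hxy = _entropy_from_counts(joint)
    return max(0.0, hx + hy - hxy)


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> float:
    """I(x;y|z) = H(x,z) + H(y,z) - H(x,y,z) - H(z)."""
    cx, nx = _encode(np.asarray(x))
    cy, ny = _encode(np.asarray(y))
    cz, nz = _encode(np.asarray(z))
    hz = _entropy_from_counts(np.bincount(cz))
    hxz = _entropy_from_counts(np.bincount(cx * nz + cz))
    hyz = _entropy_from_counts(np.bincount(cy * nz + cz))
    hxyz = _entropy_from_counts(np.bincount((cx * ny + cy) * nz + cz))
    return max(0.0, hxz + hyz - hxyz - hz)


def joint_code(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cx, _ = _encode(np.asarray(x))
    cy, ny = _encode(np.asarray(y))
    return cx * ny + cy


def equal_frequency_discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Quantile binning of a continuous feature to integer codes."""
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def discretize_matrix(x: np.ndarray, bins: int) -> np.ndarray:
    return np.stack(
        [equal_frequency_discretize(x[:, j], bins) for j in range(x.shape[1])], axis=1
    )


# --------------------------------------------------------------------------
# univariate scores
# --------------------------------------------------------------------------

def _gini_impurity(y_codes: np.ndarray, n_classes: int) -> float:
    p = np.bincount(y_codes, minlength=n_classes) / y_codes.size
    return float(1.0 - (p**2).sum())


def score_univariate(x: np.ndarray, y: np.ndarray, method: str, bins: int = 5) -> np.ndarray:
    """Per-feature relevance scores for FSCR / GINI / CHSQ / TSCR."""
    x = np.asarray(x, dtype=float)
    y_codes, n_classes = _encode(np.asarray(y))
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if method == "TSCR" and n_classes != 2:
        raise ValueError("t-score is defined for binary targets only")

    n, p = x.shape
    scores = np.zeros(p)
    if method == "FSCR":
        mu = x.mean(axis=0)
        num = np.zeros(p)
        den = np.zeros(p)
        for c in range(n_classes):
            xc = x[y_codes == c]
            num += xc.shape[0] * (xc.mean(axis=0) - mu) ** 2
            den += xc.shape[0] * xc.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(den > 0, num / den, 0.0)
    elif method == "TSCR":
        x0, x1 = x[y_codes == 0], x[y_codes == 1]
        n0, n1 = len(x0), len(x1)
        se = np.sqrt(x0.var(axis=0, ddof=1) / n0 + x1.var(axis=0, ddof=1) / n1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(x0.mean(axis=0) - x1.mean(axis=0)) / se
        scores = np.nan_to_num(t, nan=0.0, posinf=0.0)  # constant feature -> 0
    else:  # binned criteria
        base_gini = _gini_impurity(y_codes, n_classes)
        for j in range(p):
            b = equal_frequency_discretize(x[:, j], bins)
            nb = int(b.max()) + 1
            if method == "GINI":
                red = base_gini
                for v in range(nb):
                    sel = b == v
                    if sel.any():
                        red -= sel.mean() * _gini_impurity(y_codes[sel], n_classes)
                scores[j] = red
            elif method == "CHSQ":
                obs = np.bincount(b * n_classes + y_codes, minlength=nb * n_classes)
                obs = obs.reshape(nb, n_classes).astype(float)
                rows = obs.sum(1, keepdims=True)
                cols = obs.sum(0, keepdims=True)
                exp = rows * cols / obs.sum()
                with np.errstate(divide="ignore", invalid="ignore"):
                    chi = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
                scores[j] = chi.sum()
            else:
                raise ValueError(f"unknown univariate method {method!r}")
    return scores


# --------------------------------------------------------------------------
# ReliefF
# --------------------------------------------------------------------------

def relieff(
    x: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Standard ReliefF feature weights (features scaled to [0,1] internally).

    For each sampled instance the n_neighbors nearest same-class hits pull
    weights down by their feature differences and each other class's nearest
    misses push them up, weighted by the class prior.  Deterministic per seed.
    """
    x = np.asarray(x, dtype=float)
    y_codes, n_classes = _encode(np.asarray(y))
    if n_classes < 2:
        raise ValueError("need at least two classes")
    n, p = x.shape
    span = x.max(axis=0) - x.min(axis=0)
    span[span == 0] = 1.0
    xs = (x - x.min(axis=0)) / span
    priors = np.bincount(y_codes, minlength=n_classes) / n

    rng = np.random.default_rng(seed)
    m = n if n_iterations is None else min(n_iterations, n)
    order = rng.permutation(n)[:m]
    w = np.zeros(p)
    for i in order:
        d = np.abs(xs - xs[i]).sum(axis=1)
        d[i] = np.inf
        cls = y_codes[i]
        hits = np.where(y_codes == cls)[0]
        hits = hits[hits != i]
        k_h = min(n_neighbors, len(hits))
        if k_h:
            nearest = hits[np.argsort(d[hits], kind="stable")[:k_h]]
            w -= np.abs(xs[nearest] - xs[i]).sum(axis=0) / (m * k_h)
        for c in range(n_classes):
            if c == cls:
                continue
            miss = np.where(y_codes == c)[0]
            k_m = min(n_neighbors, len(miss))
            if not k_m:
                continue
            nearest = miss[np.argsort(d[miss], kind="stable")[:k_m]]
            coef = priors[c] / (1.0 - priors[cls])
            w += coef * np.abs(xs[nearest] - xs[i]).sum(axis=0) / (m * k_m)
    return w


# --------------------------------------------------------------------------
# greedy mutual-information family
# --------------------------------------------------------------------------

def greedy_mi_select(
    x_discrete: np.ndarray,
    y: np.ndarray,
    method: str,
    k: int,
    beta: float = 1.0,
) -> list[int]:
    """Forward selection under one of the eight MI criteria.

    ``x_discrete`` holds integer-coded features.  Running accumulators keep
    each step O(p) pairwise MI evaluations against the newly added feature.
    """
    if method not in MI_METHODS:
        raise ValueError(f"unknown MI method {method!r}")
    xd = np.asarray(x_discrete)
    n, p = xd.shape
    if k > p:
        raise ValueError(f"cannot select k={k} from {p} features")
    y = np.asarray(y)

    rel = np.array([mutual_information(xd[:, j], y) for j in range(p)])
    selected: list[int] = []
    remaining = np.ones(p, dtype=bool)

    acc = np.zeros(p)  # method-specific running sum
    cmim_min = np.full(p, np.inf)

    while len(selected) < k:
        if not selected:
            crit = rel.copy()
        elif method == "MIM":
            crit = rel.copy()
        elif method == "MIFS":
            crit = rel - beta * acc
        elif method == "MRMR":
            crit = rel - acc / len(selected)
        elif method in ("JMI", "DISR"):
            crit = acc.copy()
        elif method == "CIFE":
            crit = rel - acc
        elif method == "ICAP":
            crit = rel - acc
        elif method == "CMIM":
            crit = cmim_min.copy()
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # ties: lowest feature index
        selected.append(best)
        remaining[best] = False

        s = xd[:, best]
        if method in ("MIFS", "MRMR"):
            for j in np.where(remaining)[0]:
                acc[j] += mutual_information(xd[:, j], s)
        elif method in ("CIFE", "ICAP"):
            for j in np.where(remaining)[0]:
                red = mutual_information(xd[:, j], s)
                cls_red = conditional_mutual_information(xd[:, j], s, y)
                term = red - cls_red
                acc[j] += max(0.0, term) if method == "ICAP" else term
        elif method in ("JMI", "DISR"):
            for j in np.where(remaining)[0]:
                joint = joint_code(xd[:, j], s)
                mi_joint = mutual_information(joint, y)
                if method == "DISR":
                    h = entropy(joint)
                    acc[j] += mi_joint / h if h > 0 else 0.0
                else:
                    acc[j] += mi_joint
        elif method == "CMIM":
            for j in np.where(remaining)[0]:
                cmim_min[j] = min(
                    cmim_min[j],
                    conditional_mutual_information(xd[:, j], y, s),
                )
    return selected


def select_features(x: np.ndarray, y: np.ndarray, spec: SelectorSpec) -> list[int]:
    """Top-k feature indices for any of the 13 methods (training data only)."""
    x = np.asarray(x, dtype=float)
    if spec.k > x.shape[1]:
        raise ValueError(f"cannot select k={spec.k} from {x.shape[1]} features")
    if spec.method in MI_METHODS:
        xd = discretize_matrix(x, spec.discretization_bins)
        return greedy_mi_select(xd, y, spec.method, spec.k, beta=spec.mifs_beta)
    if spec.method == "RELF":
        scores = relieff(x, y, n_neighbors=spec.relieff_neighbors, seed=spec.seed)
    else:
        scores = score_univariate(x, y, spec.method, bins=spec.discretization_bins)
    order = np.argsort(-scores, kind="stable")
    return [int(j) for j in order[: spec.k]]
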