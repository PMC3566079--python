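"""Stepwise canonical discriminant analysis with centroid confidence regions.

Forward stepping by the partial Wilks-lambda F statistic with the
thresholds F-to-enter = 1 and F-to-remove = 0.9, followed by canonical
discriminant analysis (the between/within generalized eigenproblem) and
per-group 90% confidence ellipses for the centroids in the first two
canonical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2

__all__ = [
    "DiscriminantResult",
    "stepwise_select",
    "canonical_da",
    "centroid_ellipses",
    "ellipses_overlap",
]

DEFAULT_F_ENTER = 1.0
DEFAULT_F_REMOVE = 0.9
DEFAULT_CONFIDENCE = 0.90


@dataclass
class DiscriminantResult:
    selected_variables: list
    coefficients: np.ndarray        # (n_selected, n_axes)
    eigenvalues: np.ndarray
    scores: np.ndarray              # (n_animals, n_axes), grand-mean centred
    labels: list
    centroids: dict                 # label -> (n_axes,) mean score
    ellipses: dict = field(default_factory=dict)
    f_enter: float = DEFAULT_F_ENTER
    f_remove: float = DEFAULT_F_REMOVE
    confidence: float = DEFAULT_CONFIDENCE


def _scatter_matrices(X: np.ndarray, labels):
    """Within-group (W) and total (T) scatter of X (n_samples, n_vars)."""
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(labels):
        Xg = X[labels == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    return W, T


def _wilks_lambda(X, labels, cols):
    if not cols:
        return 1.0
    W, T = _scatter_matrices(X[:, cols], labels)
    detT = np.linalg.det(T)
    if detT <= 0:
        return np.nan
    return float(np.linalg.det(W) / detT)


def _partial_f(lam_small, lam_big, n, k, p_in):
    """Partial F for adding one variable to a p_in-variable model."""
    if not np.isfinite(lam_big) or lam_big <= 0:
        return np.nan
    return (n - k - p_in) / (k - 1) * (lam_small / lam_big - 1.0)


def stepwise_select(X, labels, f_enter: float = DEFAULT_F_ENTER,
                    f_remove: float = DEFAULT_F_REMOVE,
                    variable_names=None) -> list:
    """Greedy forward selection by partial Wilks-lambda F.

    At each step the candidate with the largest partial F enters if that
    F >= *f_enter*; after each entry, any included variable whose partial
    F (given the others) falls below *f_remove* is removed. Requiring
    f_remove < f_enter guarantees termination.

    Returns the ordered list of selected variable names (or indices).
    """
    X = np.asarray(X, dtype=float)
    n, nvar = X.shape
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("need at least two groups")
    if f_remove >= f_enter:
        raise ValueError("require f_remove < f_enter")
    if variable_names is None:
        variable_names = list(range(nvar))

    selected: list[int] = []
    while True:
        p_in = len(selected)
        if n - k - p_in <= 0:
            break
        lam_in = _wilks_lambda(X, labels, selected)
        # entry scan
        best, best_f = None, -np.inf
        for j in range(nvar):
            if j in selected:
                continue
            lam_j = _wilks_lambda(X, labels, selected + [j])
            fj = _partial_f(lam_in, lam_j, n, k, p_in)
            if np.isfinite(fj) and fj > best_f:
                best, best_f = j, fj
        if best is None or best_f < f_enter:
            break
        selected.append(best)
        # removal scan
        changed = True
        while changed and len(selected) > 1:
            changed = False
            lam_full = _wilks_lambda(X, labels, selected)
            for j in list(selected):
                rest = [v for v in selected if v != j]
                lam_rest = _wilks_lambda(X, labels, rest)
                fj = _partial_f(lam_rest, lam_full, n, k, len(rest))
                if np.isfinite(fj) and fj < f_remove:
                    selected.remove(j)
                    changed = True
                    break
    return [variable_names[j] for j in selected]


def canonical_da(X, labels, variable_names=None) -> DiscriminantResult:
    """Canonical discriminant axes from the between/within eigenproblem.

    Coefficients are normalized so canonical scores have identity pooled
    within-group covariance; the sign of each axis is fixed by making its
    largest-magnitude coefficient positive; scores are centred on the
    grand mean. At most min(k - 1, n_vars) axes are returned.
    """
    X = np.asarray(X, dtype=float)
    labels_arr = np.asarray(labels)
    n, nvar = X.shape
    k = len(np.unique(labels_arr))
    W, T = _scatter_matrices(X, labels_arr)
    B = T - W
    S_pooled = W / (n - k)
    try:
        evals, evecs = linalg.eigh(B, S_pooled)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"singular within-group scatter for variables {variable_names}"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(k - 1, nvar)
    evals = evals[order][:n_axes]
    A = evecs[:, order][:, :n_axes]
    # eigh(B, S) returns vectors with a' S a = 1 -> unit pooled within-cov
    for j in range(n_axes):
        i_max = np.argmax(np.abs(A[:, j]))
        if A[i_max, j] < 0:
            A[:, j] = -A[:, j]
    scores = (X - X.mean(axis=0)) @ A
    centroids = {g: scores[labels_arr == g].mean(axis=0)
                 for g in np.unique(labels_arr)}
    return DiscriminantResult(
        selected_variables=list(variable_names) if variable_names is not None
        else list(range(nvar)),
        coefficients=A, eigenvalues=evals, scores=scores,
        labels=list(labels_arr), centroids=centroids)


def centroid_ellipses(scores, labels, confidence: float = DEFAULT_CONFIDENCE
                      ) -> dict:
    """Per-group confidence ellipse for the centroid in 2D score space.

    The ellipse is the group's score covariance scaled by
    ``chi2.ppf(confidence, 2) / n_g`` — a confidence region for the mean,
    not a data-concentration ellipse. Groups with degenerate (zero)
    covariance get a zero-area ellipse with a flag.

    Returns label -> dict(center, cov, radii, angle_deg, area, flag).
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels_arr = np.asarray(labels)
    scale = chi2.ppf(confidence, df=2)
    out = {}
    for g in np.unique(labels_arr):
        S = scores[labels_arr == g]
        ng = len(S)
        if ng < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")
        center = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        covm = cov * scale / ng
        evals, evecs = np.linalg.eigh(covm)
        evals = np.clip(evals, 0.0, None)
        radii = np.sqrt(evals)[::-1]              # major, minor
        vmax = evecs[:, np.argmax(evals)]
        angle = float(np.degrees(np.arctan2(vmax[1], vmax[0])) % 180.0)
        flag = "degenerate (zero-area) ellipse" if radii[0] == 0 else None
        out[str(g)] = {
            "center": center, "cov": covm, "radii": radii,
            "angle_deg": angle, "area": float(np.pi * radii[0] * radii[1]),
            "flag": flag,
        }
    return out


def _ellipse_boundary(e, n=256):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    a, b = e["radii"]
    th = np.radians(e["angle_deg"])
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = np.stack([a * np.cos(t), b * np.sin(t)])
    return (R @ pts).T + e["center"]


def _inside(e, pts):
    d = pts - e["center"]
    th = np.radians(e["angle_deg"])
    R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    u = d @ R.T
    a, b = np.maximum(e["radii"], 1e-300)
    return (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 <= 1.0


def ellipses_overlap(e1: dict, e2: dict, n: int = 512) -> bool:
    """Whether two ellipses (as returned by centroid_ellipses) intersect.

    Checked by centre containment plus dense boundary sampling; adequate
    for the well-conditioned regions produced here.
    """
    if _inside(e2, e1["center"][None, :])[0] or \
       _inside(e1, e2["center"][None, :])[0]:
        return True
    return bool(_inside(e2, _ellipse_boundary(e1, n)).any()
                or _inside(e1, _ellipse_boundary(e2, n)).any())
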