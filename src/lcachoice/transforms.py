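"""Classification of attribute-sublayer equilibria into transform regimes.

Depending on self-feedback s and inhibition l, a sublayer's equilibrium can
(i) pass inputs through unchanged, (ii) saturate the input-maximal node at 1
while suppressing the rest (an ordinal identify-the-best comparison, or its
top-k generalization), (iii) suppress only the input-minimal node
(identify-the-worst), or (iv) stay interior and compute a relative,
normalized representation

    alpha_i = w1 * x_i - w2 * sum_{k != i} x_k

with constants w1, w2 determined by (s, l). This module classifies a
computed equilibrium, sweeps (s, l) grids into region maps, and searches the
grid for parameters that realize a target transform.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .network import ChoiceSet, EquilibriumProfile, sublayer_equilibrium

__all__ = [
    "TransformKind",
    "TransformLabel",
    "classify_transform",
    "region_map",
    "find_params_for_transform",
    "interior_weights",
]

#: activation counts as saturated at 0 or 1 within this tolerance
SATURATION_TOL = 1e-9
#: residual bound for the interior linear fit
FIT_TOL = 1e-8


class TransformKind(str, enum.Enum):
    IDENTITY = "IDENTITY"
    IDENTIFY_BEST = "IDENTIFY_BEST"
    IDENTIFY_WORST = "IDENTIFY_WORST"
    NORMALIZED = "NORMALIZED"
    IDENTIFY_K_BEST = "IDENTIFY_K_BEST"
    OTHER = "OTHER"


@dataclasses.dataclass(frozen=True)
class TransformLabel:
    """Transform regime of a sublayer equilibrium.

    ``k`` is set for IDENTIFY_K_BEST; ``params`` carries the fitted
    (w1, w2) pair for NORMALIZED.
    """

    kind: TransformKind
    k: int | None = None
    params: tuple[float, float] | None = None

    def matches(self, other: "TransformLabel") -> bool:
        """Same regime (and same k where applicable); fitted params ignored."""
        return self.kind == other.kind and (
            self.kind != TransformKind.IDENTIFY_K_BEST or self.k == other.k
        )


def interior_weights(s: float, l: float, n: int) -> tuple[float, float]:
    """Closed-form (w1, w2) of the interior (unsaturated) equilibrium.

    Solving the linear fixed point alpha_i = s*alpha_i - l*(sum-alpha_i) + x_i
    for n active nodes gives

        w1 = [1 - l / (1 - s + (n-1) l)] / (1 - s - l)
        w2 = l / [(1 - s - l) (1 - s + (n-1) l)]

    valid whenever 1 - s - l != 0 and no node is clipped.
    """
    denom = 1.0 - s - l
    shared = 1.0 - s + (n - 1) * l
    if denom == 0 or shared == 0:
        raise ValueError("degenerate (s, l): interior fixed point undefined")
    w1 = (1.0 - l / shared) / denom
    w2 = l / (denom * shared)
    return w1, w2


def _fit_linear_form(inputs: np.ndarray, alpha: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of alpha_i = w1*x_i - w2*sum_{k!=i} x_k.

    Returns (w1, w2, max absolute residual).
    """
    others = inputs.sum() - inputs
    design = np.column_stack([inputs, -others])
    coef, *_ = np.linalg.lstsq(design, alpha, rcond=None)
    resid = float(np.abs(design @ coef - alpha).max())
    return float(coef[0]), float(coef[1]), resid


def classify_transform(
    inputs,
    profile: EquilibriumProfile,
    tol: float = SATURATION_TOL,
    fit_tol: float = FIT_TOL,
    available: np.ndarray | None = None,
) -> TransformLabel:
    """Classify a converged sublayer equilibrium into its transform regime.

    ``inputs`` are the attribute values of the considered alternatives, in
    the same order as the considered entries of ``profile.alpha``. Ties in
    the inputs make ordinal regimes undefined and classify as OTHER.
    """
    if not profile.converged:
        raise ValueError("cannot classify an unconverged equilibrium profile")
    inputs = np.asarray(inputs, dtype=float).ravel()
    alpha = np.asarray(profile.alpha, dtype=float)
    if available is not None:
        alpha = alpha[np.asarray(available, dtype=bool)]
    if alpha.shape != inputs.shape:
        raise ValueError("inputs and equilibrium activations differ in length")
    n = inputs.size
    if np.unique(inputs).size != n:
        return TransformLabel(TransformKind.OTHER)

    if np.all(np.abs(alpha - inputs) <= tol):
        return TransformLabel(TransformKind.IDENTITY)

    at_one = alpha >= 1.0 - tol
    at_zero = alpha <= tol
    order = np.argsort(-inputs)  # decreasing input value
    if np.all(at_one | at_zero):
        k = int(at_one.sum())
        if 1 <= k <= n - 1 and np.all(at_one[order[:k]]):
            if k == 1:
                return TransformLabel(TransformKind.IDENTIFY_BEST)
            return TransformLabel(TransformKind.IDENTIFY_K_BEST, k=k)
        return TransformLabel(TransformKind.OTHER)

    worst = order[-1]
    if alpha[worst] <= tol and np.all(np.delete(alpha, worst) > tol):
        return TransformLabel(TransformKind.IDENTIFY_WORST)

    if np.all((alpha > tol) & (alpha < 1.0 - tol)):
        w1, w2, resid = _fit_linear_form(inputs, alpha)
        if resid < fit_tol and w1 > 0 and w2 >= -fit_tol:
            return TransformLabel(TransformKind.NORMALIZED, params=(w1, max(w2, 0.0)))
    return TransformLabel(TransformKind.OTHER)


def _equilibrium_for(inputs: np.ndarray, s: float, l: float, **kw) -> EquilibriumProfile:
    cs = ChoiceSet(values=np.asarray(inputs, dtype=float)[:, None], weights=[1.0])
    return sublayer_equilibrium(cs, 0, s, l, **kw)


def region_map(
    inputs,
    s_grid=None,
    l_grid=None,
    step: float = 0.01,
) -> pd.DataFrame:
    """Sweep an (s, l) grid and classify each cell's equilibrium.

    Returns a long-format frame with columns s, l, label, k, omega1, omega2,
    converged and alpha_1..alpha_n. Unconverged cells are labeled OTHER with
    ``converged`` False. Default grids cover [0, 1] with inclusive endpoints.
    """
    inputs = np.asarray(inputs, dtype=float).ravel()
    if s_grid is None:
        s_grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    if l_grid is None:
        l_grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    rows = []
    for s in np.asarray(s_grid, dtype=float):
        for l in np.asarray(l_grid, dtype=float):
            prof = _equilibrium_for(inputs, s, l)
            if prof.converged:
                label = classify_transform(inputs, prof)
            else:
                label = TransformLabel(TransformKind.OTHER)
            row = {
                "s": s,
                "l": l,
                "label": label.kind.value,
                "k": label.k,
                "omega1": label.params[0] if label.params else np.nan,
                "omega2": label.params[1] if label.params else np.nan,
                "converged": prof.converged,
            }
            for i, a in enumerate(prof.alpha, start=1):
                row[f"alpha_{i}"] = a
            rows.append(row)
    return pd.DataFrame(rows)


def find_params_for_transform(
    inputs,
    target: TransformLabel | TransformKind,
    grid_step: float = 0.01,
    s_max: float = 1.0,
    l_max: float = 1.0,
) -> tuple[float, float] | None:
    """Grid-search (s, l) for the first pair realizing a target transform.

    Scans lexicographically (s ascending, then l) over inclusive grids from
    0 to ``s_max``/``l_max`` and returns the first (s, l) whose equilibrium
    classifies as ``target``, or None when no grid cell matches.
    """
    if not (0.0 < grid_step < 1.0):
        raise ValueError("grid_step must be in (0, 1)")
    if isinstance(target, TransformKind):
        target = TransformLabel(target)
    inputs = np.asarray(inputs, dtype=float).ravel()
    s_grid = np.round(np.arange(0.0, s_max + grid_step / 2, grid_step), 10)
    l_grid = np.round(np.arange(0.0, l_max + grid_step / 2, grid_step), 10)
    for s in s_grid:
        for l in l_grid:
            prof = _equilibrium_for(inputs, float(s), float(l))
            if not prof.converged:
                continue
            if classify_transform(inputs, prof).matches(target):
                return float(s), float(l)
    return None
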