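"""Network parameter presets mimicking heuristic choice rules, and the
idealized (symbolic) heuristics they are compared against.

Presets follow the recipes that make the accumulator network reproduce a
heuristic: ordinal rules (LEX, CONF/k-CONF, WP, MCD) use identify-the-best
sublayers; value-integrating rules (EW, WAD) pass raw values through with
s_A = l_A = 0; memoryless acceptance (s_P = 0) plus Q = max(w) yields LEX,
while perfect memory (s_P = 1) with a high threshold yields the exhaustive
rules. The idealized oracles are deterministic and return UNDEFINED (None)
on any tie relevant to the rule — never a silent tie-break.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .network import ChoiceSet, NetworkParams, sublayer_equilibrium
from .transforms import (
    TransformKind,
    TransformLabel,
    classify_transform,
    find_params_for_transform,
)

__all__ = [
    "HEURISTIC_NAMES",
    "DETERMINISTIC_HEURISTICS",
    "HeuristicPreset",
    "preset_params",
    "idealized_choice",
]

HEURISTIC_NAMES = ("LEX", "CONF", "K_CONF", "WP", "MCD", "EW", "WAD", "ITW", "K_MCD")
#: heuristics with deterministic idealized predictions (CONF excluded: its
#: prediction depends on the random order in which attributes are sampled)
DETERMINISTIC_HEURISTICS = ("LEX", "WP", "MCD", "EW", "WAD", "ITW")

_EQUAL_WEIGHT_RULES = {"CONF", "K_CONF", "MCD", "EW", "K_MCD"}
_ORDINAL_RULES = {"LEX", "CONF", "K_CONF", "WP", "MCD"}


@dataclasses.dataclass(frozen=True)
class HeuristicPreset:
    """A named network parameterization mimicking one heuristic."""

    name: str
    params: NetworkParams
    weights: np.ndarray
    k: int | None = None


def _check_equal(weights: np.ndarray, name: str) -> None:
    if not np.all(weights == weights[0]):
        raise ValueError(f"{name} requires equal attribute weights")


def _sublayer_for_target(
    choice_set: ChoiceSet, target: TransformLabel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-attribute (s_A, l_A) realizing ``target`` on every sublayer.

    Ordinal identify-the-best targets first try the study value (1, 1) and
    fall back to a grid search only where (1, 1) fails to classify; other
    targets go straight to the search.
    """
    m = choice_set.n_attributes
    s_out = np.empty(m)
    l_out = np.empty(m)
    for j in range(m):
        inputs = choice_set.values[:, j]
        if target.kind == TransformKind.IDENTIFY_BEST:
            prof = sublayer_equilibrium(choice_set, j, 1.0, 1.0)
            if prof.converged and classify_transform(
                inputs, prof, available=choice_set.available
            ).matches(target):
                s_out[j], l_out[j] = 1.0, 1.0
                continue
        found = find_params_for_transform(inputs, target)
        if found is None:
            raise ValueError(
                f"no (s_A, l_A) on the grid realizes {target.kind.value} "
                f"for attribute {j}"
            )
        s_out[j], l_out[j] = found
    return s_out, l_out


def preset_params(
    name: str,
    weights,
    choice_set: ChoiceSet | None = None,
    Q_high: float = 0.99,
    k: int | None = None,
    T_max: int = 10_000,
) -> HeuristicPreset:
    """Build the network parameterization mimicking one heuristic.

    ``choice_set`` is only needed when sublayer parameters must be tailored
    to the alternatives at hand (always for ITW and K_MCD; for the ordinal
    rules it enables verification that the default s_A = l_A = 1 actually
    identifies the best alternative, with a grid-search fallback). Without
    it, ordinal rules use the study values (1, 1) unverified.
    """
    name = name.upper().replace("-", "_")
    if name not in HEURISTIC_NAMES:
        raise ValueError(f"unknown heuristic {name!r}; expected one of {HEURISTIC_NAMES}")
    weights = np.asarray(weights, dtype=float).ravel()
    if name in _EQUAL_WEIGHT_RULES:
        _check_equal(weights, name)
    if name == "CONF":
        k = 2
    if name in ("K_CONF", "K_MCD") and (k is None or k < 1):
        raise ValueError(f"{name} needs a positive k")

    if name in _ORDINAL_RULES:
        if choice_set is not None:
            s_A, l_A = _sublayer_for_target(
                choice_set, TransformLabel(TransformKind.IDENTIFY_BEST)
            )
        else:
            s_A, l_A = 1.0, 1.0
    elif name in ("EW", "WAD"):
        s_A, l_A = 0.0, 0.0
    elif name == "ITW":
        if choice_set is None:
            raise ValueError("ITW needs the choice set to tailor its sublayers")
        s_A, l_A = _sublayer_for_target(
            choice_set, TransformLabel(TransformKind.IDENTIFY_WORST)
        )
    else:  # K_MCD
        if choice_set is None:
            raise ValueError("K_MCD needs the choice set to tailor its sublayers")
        target = (
            TransformLabel(TransformKind.IDENTIFY_BEST)
            if k == 1
            else TransformLabel(TransformKind.IDENTIFY_K_BEST, k=k)
        )
        s_A, l_A = _sublayer_for_target(choice_set, target)

    if name == "LEX":
        s_P, Q = 0.0, float(weights.max())
    elif name in ("CONF", "K_CONF"):
        w = float(weights[0])
        if not (w < 1.0 / k):
            raise ValueError(f"{name} requires w < 1/k (got w={w}, k={k})")
        s_P, Q = 1.0, k * w
    else:
        s_P, Q = 1.0, float(Q_high)

    params = NetworkParams(s_P=s_P, l_P=0.0, s_A=s_A, l_A=l_A, Q=Q, T_max=T_max)
    return HeuristicPreset(name=name, params=params, weights=weights, k=k)


def _argmax_unique(scores: np.ndarray) -> int | None:
    top = scores.max()
    winners = np.flatnonzero(scores == top)
    return int(winners[0]) if winners.size == 1 else None


def _best_on_attribute(values: np.ndarray, j: int) -> int | None:
    return _argmax_unique(values[:, j])


def idealized_choice(name: str, choice_set: ChoiceSet, k: int | None = None) -> int | None:
    """Deterministic symbolic prediction of a heuristic, or None (UNDEFINED).

    Indices refer to the N possible alternatives. CONF/k-CONF are rejected:
    their outcome depends on the attribute sampling order, so there is no
    deterministic prediction to return.
    """
    name = name.upper().replace("-", "_")
    if name in ("CONF", "K_CONF"):
        raise ValueError(f"{name} makes no deterministic prediction")
    if name not in DETERMINISTIC_HEURISTICS:
        raise ValueError(f"unknown deterministic heuristic {name!r}")
    values = choice_set.values
    weights = choice_set.weights
    n, m = values.shape

    if name == "LEX":
        local = _argmax_unique(values[:, int(np.argmax(weights))])
    elif name in ("WP", "MCD"):
        indicator = np.zeros((n, m))
        for j in range(m):
            best = _best_on_attribute(values, j)
            if best is None:
                return None
            indicator[best, j] = 1.0
        scores = indicator @ weights if name == "WP" else indicator.sum(axis=1)
        local = _argmax_unique(scores)
    elif name == "EW":
        local = _argmax_unique(values.sum(axis=1))
    elif name == "WAD":
        local = _argmax_unique(values @ weights)
    else:  # ITW: weighted sums excluding each attribute's worst alternative
        keep = np.ones((n, m))
        for j in range(m):
            worst = _argmax_unique(-values[:, j])
            if worst is None:
                return None
            keep[worst, j] = 0.0
        local = _argmax_unique((values * keep) @ weights)
    if local is None:
        return None
    return int(choice_set.considered_indices[local])
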