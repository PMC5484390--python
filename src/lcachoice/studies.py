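"""Simulation studies: heuristic identification and parameter recovery.

The identification study simulates each heuristic preset on a batch of
random choice sets and scores how often its modal Monte-Carlo choice
matches each idealized heuristic's deterministic prediction (restricted to
sets where that prediction is unique). The recovery study enumerates a grid
of network parameterizations, simulates each twice on the same choice sets
(a "data" run and an independent "model" run), and measures parameter
uniqueness: the proportion of grid points that are the strict
minimum-mean-squared-error fit to the choice probabilities they themselves
generated.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

from .heuristics import idealized_choice, preset_params
from .network import ChoiceSet, NetworkParams, _fixed_point, estimate_choice_probabilities

logger = logging.getLogger(__name__)

__all__ = [
    "RecoveryConfig",
    "StudyResult",
    "generate_choice_sets",
    "run_identification_study",
    "run_recovery_study",
]

IDENTIFICATION_PRESETS = ("LEX", "WP", "MCD", "EW", "WAD")


def generate_choice_sets(
    n_sets: int,
    n_alternatives: int,
    n_attributes: int,
    rng: np.random.Generator,
    weights=None,
) -> list[ChoiceSet]:
    """Random choice sets with iid uniform(0, 1) attribute values.

    Draws are clipped away from exact 0/1 by machine epsilon to honor the
    open-interval requirement. ``weights`` defaults to equal weights 1/M.
    """
    if n_sets < 1 or n_alternatives < 1 or n_attributes < 1:
        raise ValueError("n_sets, n_alternatives and n_attributes must be positive")
    if weights is None:
        weights = np.full(n_attributes, 1.0 / n_attributes)
    eps = np.finfo(float).eps
    draws = rng.uniform(0.0, 1.0, size=(n_sets, n_alternatives, n_attributes))
    draws = np.clip(draws, eps, 1.0 - eps)
    return [ChoiceSet(values=draws[i], weights=weights) for i in range(n_sets)]


@dataclasses.dataclass(frozen=True)
class RecoveryConfig:
    """Configuration of the parameter-recovery (uniqueness) study.

    The default grid crosses s_A, l_A and Q over 0.1..0.9 in steps of 0.1
    with s_P = 1, l_P = 0 and equal weights 0.01 on two attributes, plus one
    extra memoryless ordinal combination (s_P = l_P = 0, s_A = l_A = 1,
    Q = w_1) — 9^3 + 1 = 730 parameter combinations in total.
    """

    grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
    s_P: float = 1.0
    l_P: float = 0.0
    weights: tuple[float, ...] = (0.01, 0.01)
    include_lex_combo: bool = True
    n_reps: int = 10_000
    T_max: int = 10_000

    def combos(self) -> list[NetworkParams]:
        out = [
            NetworkParams(s_P=self.s_P, l_P=self.l_P, s_A=s_A, l_A=l_A, Q=Q,
                          T_max=self.T_max)
            for s_A, l_A, Q in itertools.product(self.grid, self.grid, self.grid)
        ]
        if self.include_lex_combo:
            out.append(
                NetworkParams(s_P=0.0, l_P=0.0, s_A=1.0, l_A=1.0,
                              Q=float(self.weights[0]), T_max=self.T_max)
            )
        return out


@dataclasses.dataclass
class StudyResult:
    """Results of a simulation study.

    ``accuracy`` (identification): preset rows by idealized-heuristic
    columns, each cell the proportion of uniquely-predicted sets on which
    the preset's modal choice matched. ``uniqueness_curve`` (recovery): maps
    a number of choice sets to (uniquely recovered combos, total combos).
    """

    seed: int | None
    config: dict
    accuracy: pd.DataFrame | None = None
    evaluated_set_counts: dict[str, int] | None = None
    uniqueness_curve: dict[int, tuple[int, int]] | None = None

    def uniqueness_proportions(self) -> dict[int, float]:
        if self.uniqueness_curve is None:
            return {}
        return {n: k / total for n, (k, total) in self.uniqueness_curve.items()}


class _EquilibriumCache:
    """Weighted-input matrices V keyed by (set index, s_A, l_A) profile."""

    def __init__(self, choice_sets: list[ChoiceSet]):
        self.choice_sets = choice_sets
        self._cache: dict[tuple, np.ndarray] = {}
        self.n_unconverged = 0

    def inputs(self, set_idx: int, params: NetworkParams, weights: np.ndarray) -> np.ndarray:
        cs = self.choice_sets[set_idx]
        m = cs.n_attributes
        s_arr, l_arr = params.sublayer_params(m)
        key = (set_idx, tuple(s_arr), tuple(l_arr))
        alpha = self._cache.get(key)
        if alpha is None:
            cols = []
            for j in range(m):
                a, conv, _, resid = _fixed_point(
                    cs.sublayer_inputs(j), float(s_arr[j]), float(l_arr[j])
                )
                if not conv[0]:
                    self.n_unconverged += 1
                    logger.warning(
                        "unconverged sublayer equilibrium (set %d, attribute "
                        "%d, s=%.3g, l=%.3g, residual=%.3g); using final state",
                        set_idx, j, s_arr[j], l_arr[j], resid[0],
                    )
                cols.append(a)
            alpha = np.stack(cols)  # (M, N)
            self._cache[key] = alpha
        return weights[:, None] * alpha


def run_identification_study(
    n_sets: int = 100,
    n_reps: int = 10_000,
    seed: int | None = None,
    weights=(0.03, 0.015, 0.01),
    presets=IDENTIFICATION_PRESETS,
    idealized=IDENTIFICATION_PRESETS,
    n_alternatives: int = 3,
    rng: np.random.Generator | None = None,
) -> StudyResult:
    """Heuristic-identification study (accuracy matrix).

    Generates ``n_sets`` uniform random choice sets, computes each idealized
    heuristic's prediction, simulates every preset ``n_reps`` times per set,
    and scores modal-choice agreement on the sets where the idealized
    prediction is unique. Modal ties count as mismatch. Equal-weight presets
    (MCD, EW) use the smallest proportional weight for every attribute.
    """
    if n_sets < 1:
        raise ValueError("the study needs at least one choice set")
    if "CONF" in idealized or "K_CONF" in idealized:
        raise ValueError("CONF has no deterministic idealized prediction")
    weights = np.asarray(weights, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    sets = generate_choice_sets(n_sets, n_alternatives, weights.size, rng, weights)
    cache = _EquilibriumCache(sets)
    equal_w = np.full(weights.size, weights.min())

    oracle = {
        h: [idealized_choice(h, cs) for cs in sets] for h in idealized
    }
    counts = {h: sum(p is not None for p in oracle[h]) for h in idealized}
    for h, c in counts.items():
        if c == 0:
            raise ValueError(f"no choice set has a unique {h} prediction")

    acc = pd.DataFrame(index=list(presets), columns=list(idealized), dtype=float)
    for p_name in presets:
        w = equal_w if p_name in ("MCD", "EW", "CONF") else weights
        preset = preset_params(p_name, w)
        modal = []
        for i, cs in enumerate(sets):
            cs_w = dataclasses.replace(cs, weights=w)
            V = cache.inputs(i, preset.params, w)
            est = estimate_choice_probabilities(
                cs_w, preset.params, n_reps, rng, precomputed_inputs=V
            )
            modal.append(est.modal_choice())
        for h in idealized:
            hits = sum(
                1
                for mo, pr in zip(modal, oracle[h])
                if pr is not None and mo == pr
            )
            acc.loc[p_name, h] = hits / counts[h]
    return StudyResult(
        seed=seed,
        config={
            "n_sets": n_sets,
            "n_reps": n_reps,
            "weights": weights.tolist(),
            "presets": list(presets),
            "idealized": list(idealized),
            "n_alternatives": n_alternatives,
        },
        accuracy=acc,
        evaluated_set_counts=counts,
    )


def _mse_matrix(data: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Cell-wise MSE between every data row-block and every model row-block.

    ``data`` and ``model`` have shape (C, F) where F flattens (set,
    alternative) cells. Computed with explicit differences (no factored
    matrix products) so that exactly identical probability vectors produce
    exactly tied MSEs.
    """
    c = data.shape[0]
    out = np.empty((c, c))
    chunk = max(1, 2**22 // (data.shape[1] * c))
    for start in range(0, c, chunk):
        block = data[start : start + chunk]
        diff = block[:, None, :] - model[None, :, :]
        out[start : start + chunk] = np.mean(diff * diff, axis=2)
    return out


def run_recovery_study(
    config: RecoveryConfig,
    n_sets_list,
    seed: int | None = None,
    n_alternatives: int = 3,
    rng: np.random.Generator | None = None,
    combos: list[NetworkParams] | None = None,
) -> StudyResult:
    """Parameter-recovery study (uniqueness curve).

    For the largest requested number of choice sets, generates that many
    uniform random sets and simulates every parameter combination twice on
    each (independent data and model runs, ``config.n_reps`` repetitions
    each). For each curve point the first n sets are used: a combination
    counts as uniquely recovered when it is the strict unique minimizer of
    the mean-squared error between its data probabilities and every
    combination's model probabilities.
    """
    n_sets_list = sorted(int(n) for n in n_sets_list)
    if not n_sets_list or n_sets_list[0] < 1:
        raise ValueError("n_sets_list must contain positive set counts")
    if combos is None:
        combos = config.combos()
    weights = np.asarray(config.weights, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_max = n_sets_list[-1]
    sets = generate_choice_sets(n_max, n_alternatives, weights.size, rng, weights)
    cache = _EquilibriumCache(sets)

    c = len(combos)
    data = np.empty((c, n_max, n_alternatives))
    model = np.empty((c, n_max, n_alternatives))
    for ci, params in enumerate(combos):
        for si, cs in enumerate(sets):
            V = cache.inputs(si, params, weights)
            for out in (data, model):
                est = estimate_choice_probabilities(
                    cs, params, config.n_reps, rng, precomputed_inputs=V
                )
                out[ci, si] = est.probabilities
    if cache.n_unconverged:
        logger.info("%d unconverged sublayer equilibria in recovery study",
                    cache.n_unconverged)

    curve: dict[int, tuple[int, int]] = {}
    for n in n_sets_list:
        d = data[:, :n, :].reshape(c, -1)
        mo = model[:, :n, :].reshape(c, -1)
        mse = _mse_matrix(d, mo)
        unique = 0
        for ci in range(c):
            row = mse[ci]
            best = row.min()
            winners = np.flatnonzero(row == best)
            if winners.size == 1 and winners[0] == ci:
                unique += 1
        curve[n] = (unique, c)
    return StudyResult(
        seed=seed,
        config={
            "grid": list(config.grid),
            "weights": weights.tolist(),
            "n_reps": config.n_reps,
            "n_sets_list": n_sets_list,
            "n_alternatives": n_alternatives,
            "n_combos": c,
        },
        uniqueness_curve=curve,
    )
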