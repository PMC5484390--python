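"""Core data model and dynamics of the two-layer accumulator network.

The network has M attribute-representation sublayers feeding a single
preference-accumulation layer. Every node uses the same piecewise-linear
activation bounded at 0 and 1, and every layer updates synchronously with
self-feedback ``s`` and lateral inhibition ``l``::

    X_i(t) = f[ s * X_i(t-1) - l * sum_{k != i} X_k(t-1) + Y_i(t) ]

Attribute sublayers run on a fast timescale and are replaced by their
equilibrium activations; a decision is a race of preference accumulators,
fed at each sampling step by one randomly chosen attribute's weighted
equilibrium, until some preference reaches the acceptance threshold Q.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "ChoiceSet",
    "NetworkParams",
    "EquilibriumProfile",
    "DecisionOutcome",
    "ChoiceProbabilities",
    "piecewise_linear",
    "layer_step",
    "sublayer_equilibrium",
    "attribute_inputs",
    "simulate_decision",
    "estimate_choice_probabilities",
    "utility",
]

#: default fixed-point tolerance for sublayer equilibria
EQUILIBRIUM_TOL = 1e-10
#: default iteration cap for sublayer equilibria
EQUILIBRIUM_MAX_ITER = 10_000


def piecewise_linear(y):
    """Piecewise-linear activation bounded at 0 and 1.

    Returns 1 for y > 1, y for 0 <= y <= 1 and 0 for y < 0; applied
    elementwise to array input. Non-finite input is rejected.
    """
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input to activation function")
    out = np.clip(arr, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclasses.dataclass(frozen=True)
class ChoiceSet:
    """A multi-attribute choice set.

    Parameters
    ----------
    values
        Matrix of attribute values, one row per *considered* alternative and
        one column per attribute; every entry strictly inside (0, 1).
    weights
        Nonnegative attribute weights, one per attribute, at least one
        positive.
    available
        Optional boolean mask over the N possible alternatives; exactly
        ``values.shape[0]`` entries must be True, and row k of ``values``
        describes the k-th available alternative. Defaults to all available
        (N equals the number of rows).
    """

    values: np.ndarray
    weights: np.ndarray
    available: np.ndarray | None = None

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        weights = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D matrix")
        if np.any(values <= 0.0) or np.any(values >= 1.0):
            bad = np.argwhere((values <= 0.0) | (values >= 1.0))[0]
            raise ValueError(
                f"attribute value at row {bad[0]}, column {bad[1]} is outside "
                f"the open interval (0, 1): {values[bad[0], bad[1]]!r}"
            )
        if weights.shape[0] != values.shape[1]:
            raise ValueError(
                f"{weights.shape[0]} weights for {values.shape[1]} attributes"
            )
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be nonnegative with at least one positive")
        if self.available is None:
            mask = np.ones(values.shape[0], dtype=bool)
        else:
            mask = np.asarray(self.available, dtype=bool).ravel()
            if mask.sum() != values.shape[0]:
                raise ValueError(
                    f"availability mask selects {int(mask.sum())} alternatives "
                    f"but values has {values.shape[0]} rows"
                )
        object.__setattr__(self, "available", mask)

    @property
    def n_alternatives(self) -> int:
        """Number of possible alternatives N (nodes per layer)."""
        return int(self.available.shape[0])

    @property
    def n_considered(self) -> int:
        """Number of available alternatives n."""
        return int(self.values.shape[0])

    @property
    def n_attributes(self) -> int:
        return int(self.values.shape[1])

    @property
    def considered_indices(self) -> np.ndarray:
        """Indices (into the N possible alternatives) of the available ones."""
        return np.flatnonzero(self.available)

    def sublayer_inputs(self, attribute: int) -> np.ndarray:
        """Exogenous input vector y_j of length N for one attribute sublayer.

        y_ij = x_ij for available alternatives, 0 otherwise.
        """
        y = np.zeros(self.n_alternatives)
        y[self.considered_indices] = self.values[:, attribute]
        return y


def utility(choice_set: ChoiceSet) -> np.ndarray:
    """Weighted additive utility U_i = sum_j w_j * x_ij per considered row."""
    return choice_set.values @ choice_set.weights


@dataclasses.dataclass(frozen=True)
class NetworkParams:
    """All recurrent and threshold parameters of both layers.

    ``s_A``/``l_A`` may be scalars (shared across sublayers) or one value per
    attribute. ``sampling_probs`` is the probability of sampling each
    attribute at a step (default uniform).
    """

    s_P: float
    l_P: float
    s_A: float | Sequence[float]
    l_A: float | Sequence[float]
    Q: float
    T_max: int = 10_000
    sampling_probs: Sequence[float] | None = None

    def __post_init__(self):
        if not (0.0 < self.Q <= 1.0):
            raise ValueError(f"Q must be in (0, 1], got {self.Q}")
        if self.T_max < 1:
            raise ValueError("T_max must be at least 1")
        if self.s_P < 0 or self.l_P < 0:
            raise ValueError("s_P and l_P must be nonnegative")
        for name in ("s_A", "l_A"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.sampling_probs is not None:
            p = np.asarray(self.sampling_probs, dtype=float)
            if np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("sampling_probs must be positive and sum to 1")
            object.__setattr__(self, "sampling_probs", p)

    def sublayer_params(self, n_attributes: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-attribute (s_Aj, l_Aj) arrays, broadcasting scalars."""
        s = np.broadcast_to(np.asarray(self.s_A, dtype=float), (n_attributes,)).copy()
        l = np.broadcast_to(np.asarray(self.l_A, dtype=float), (n_attributes,)).copy()
        return s, l

    def attribute_probs(self, n_attributes: int) -> np.ndarray:
        if self.sampling_probs is None:
            return np.full(n_attributes, 1.0 / n_attributes)
        p = np.asarray(self.sampling_probs, dtype=float)
        if p.shape[0] != n_attributes:
            raise ValueError("sampling_probs length does not match attributes")
        return p


@dataclasses.dataclass(frozen=True)
class EquilibriumProfile:
    """Stable activations of one attribute sublayer.

    ``alpha`` has length N (entries for unavailable alternatives are 0).
    ``converged`` is False when the synchronous iteration hit the iteration
    cap or entered a period-2 cycle; the final state is still reported.
    """

    alpha: np.ndarray
    converged: bool
    iterations: int
    residual: float


def layer_step(state, inputs, s: float, l: float):
    """One synchronous update of a leaky competitive layer.

    Node i receives ``s*X_i - l*sum_{k!=i} X_k + Y_i`` passed through the
    piecewise-linear activation.
    """
    state = np.asarray(state, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if state.shape != inputs.shape:
        raise ValueError("state and inputs must have the same length")
    total = state.sum()
    return piecewise_linear(s * state - l * (total - state) + inputs)


def _fixed_point(
    y: np.ndarray,
    s: float,
    l: float,
    tol: float = EQUILIBRIUM_TOL,
    max_iter: int = EQUILIBRIUM_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Synchronous fixed-point iteration from zero for one or more sublayers.

    ``y`` has shape (N, K): K independent sublayers sharing (s, l), iterated
    simultaneously. Returns (alpha, converged, iterations, residual), the
    last three of length K. A period-2 cycle (state equal to the state two
    steps back while still changing) terminates that run unconverged.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n, k = y.shape
    X = np.zeros((n, k))
    prev = np.full((n, k), np.nan)  # state two steps back
    converged = np.zeros(k, dtype=bool)
    cycling = np.zeros(k, dtype=bool)
    iterations = np.full(k, max_iter, dtype=int)
    residual = np.full(k, np.inf)
    Xn = X
    for it in range(1, max_iter + 1):
        total = X.sum(axis=0)
        Xn = np.clip(s * X + l * X - l * total + y, 0.0, 1.0)
        resid = np.abs(Xn - X).max(axis=0)
        settled = converged | cycling
        newly = ~settled & (resid < tol)
        converged |= newly
        iterations[newly] = it
        residual[newly] = resid[newly]
        # period-2 cycle: back where we were two steps ago while still moving
        # by far more than tol (slow geometric convergence also revisits the
        # two-steps-back neighborhood, so require a clearly non-trivial step)
        cyc = (
            ~(settled | newly)
            & (np.abs(Xn - prev).max(axis=0) < tol)
            & (resid > 1e3 * tol)
        )
        cycling |= cyc
        iterations[cyc] = it
        residual[cyc] = resid[cyc]
        unsettled = ~(converged | cycling)
        residual[unsettled] = resid[unsettled]
        if not np.any(unsettled):
            break
        prev = X
        X = Xn
    alpha = Xn
    if squeeze:
        return alpha[:, 0], converged, iterations, residual
    return alpha, converged, iterations, residual


def sublayer_equilibrium(
    choice_set: ChoiceSet,
    attribute: int,
    s: float,
    l: float,
    tol: float = EQUILIBRIUM_TOL,
    max_iter: int = EQUILIBRIUM_MAX_ITER,
) -> EquilibriumProfile:
    """Equilibrium activations of one attribute sublayer.

    Iterates the synchronous update from the all-zero state with constant
    inputs y_j until the max absolute change drops below ``tol`` or
    ``max_iter`` is reached. Non-convergence is reported in the profile,
    never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    y = choice_set.sublayer_inputs(attribute)
    alpha, conv, iters, resid = _fixed_point(y, s, l, tol=tol, max_iter=max_iter)
    if not conv[0]:
        logger.warning(
            "sublayer equilibrium did not converge (attribute %d, s=%.3g, "
            "l=%.3g, residual=%.3g)", attribute, s, l, resid[0],
        )
    return EquilibriumProfile(
        alpha=alpha, converged=bool(conv[0]), iterations=int(iters[0]),
        residual=float(resid[0]),
    )


def attribute_inputs(
    choice_set: ChoiceSet,
    params: NetworkParams,
    tol: float = EQUILIBRIUM_TOL,
    max_iter: int = EQUILIBRIUM_MAX_ITER,
) -> tuple[np.ndarray, list[EquilibriumProfile]]:
    """Weighted equilibrium inputs V (shape M x N) to the preference layer.

    Row j holds w_j * alpha_j; equilibria are computed once per attribute
    and reused for every sampling step of a decision (the fast-timescale
    assumption makes them constant within a decision).
    """
    m = choice_set.n_attributes
    s_arr, l_arr = params.sublayer_params(m)
    profiles: list[EquilibriumProfile | None] = [None] * m
    # group attributes sharing (s, l) so they iterate in one array
    groups: dict[tuple[float, float], list[int]] = {}
    for j in range(m):
        groups.setdefault((float(s_arr[j]), float(l_arr[j])), []).append(j)
    for (s, l), idx in groups.items():
        y = np.column_stack([choice_set.sublayer_inputs(j) for j in idx])
        alpha, conv, iters, resid = _fixed_point(y, s, l, tol=tol, max_iter=max_iter)
        for col, j in enumerate(idx):
            if not conv[col]:
                logger.warning(
                    "sublayer equilibrium did not converge (attribute %d, "
                    "s=%.3g, l=%.3g, residual=%.3g)", j, s, l, resid[col],
                )
            profiles[j] = EquilibriumProfile(
                alpha=alpha[:, col], converged=bool(conv[col]),
                iterations=int(iters[col]), residual=float(resid[col]),
            )
    V = np.stack([choice_set.weights[j] * profiles[j].alpha for j in range(m)])
    return V, profiles  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class DecisionOutcome:
    """Result of a single simulated decision.

    ``chosen`` is the alternative index, or None when the decision was
    censored at T_max without any threshold crossing.
    """

    chosen: int | None
    decision_time: int
    trajectory: np.ndarray | None = None
    sampled_attributes: np.ndarray | None = None

    @property
    def censored(self) -> bool:
        return self.chosen is None


def simulate_decision(
    choice_set: ChoiceSet,
    params: NetworkParams,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> DecisionOutcome:
    """Simulate one decision, one attribute sample per step.

    The preference layer starts at zero; each step one attribute is sampled
    iid (by ``params.sampling_probs``), its cached sublayer equilibrium
    enters as weighted input, and the first step at which any available
    preference reaches Q (inclusive) terminates the decision. Simultaneous
    crossings break uniformly at random; T_max without a crossing censors.
    """
    if choice_set.n_considered == 0:
        raise ValueError("choice set has no available alternatives")
    m = choice_set.n_attributes
    V, _ = attribute_inputs(choice_set, params)
    probs = params.attribute_probs(m)
    avail = choice_set.available
    X = np.zeros(choice_set.n_alternatives)
    traj = [] if record_trajectory else None
    sampled = [] if record_trajectory else None
    for t in range(1, params.T_max + 1):
        j = int(rng.choice(m, p=probs))
        X = np.clip(params.s_P * X - params.l_P * (X.sum() - X) + V[j], 0.0, 1.0)
        if record_trajectory:
            traj.append(X.copy())
            sampled.append(j)
        crossers = np.flatnonzero(avail & (X >= params.Q))
        if crossers.size:
            chosen = int(crossers[0]) if crossers.size == 1 else int(rng.choice(crossers))
            return DecisionOutcome(
                chosen=chosen,
                decision_time=t,
                trajectory=np.asarray(traj) if record_trajectory else None,
                sampled_attributes=np.asarray(sampled) if record_trajectory else None,
            )
    return DecisionOutcome(
        chosen=None,
        decision_time=params.T_max,
        trajectory=np.asarray(traj) if record_trajectory else None,
        sampled_attributes=np.asarray(sampled) if record_trajectory else None,
    )


@dataclasses.dataclass(frozen=True)
class ChoiceProbabilities:
    """Monte-Carlo choice probabilities over the N possible alternatives."""

    probabilities: np.ndarray
    mean_decision_time: float
    censored_fraction: float
    n_reps: int

    def modal_choice(self) -> int | None:
        """Alternative with the highest probability; None on an exact tie."""
        p = self.probabilities
        top = p.max()
        winners = np.flatnonzero(p == top)
        return int(winners[0]) if winners.size == 1 else None


@njit(cache=True)
def _race_kernel(V, cum_probs, Q, T_max, n_reps, seed, s_P, l_P):  # pragma: no cover
    """Compiled batch of independent decision races.

    Runs the exact per-step preference dynamics (same recurrence as
    :func:`simulate_decision`) for ``n_reps`` trials with early exit at the
    first threshold crossing. ``V`` is the (M, n) weighted-equilibrium input
    matrix over considered alternatives; ``cum_probs`` the cumulative
    attribute-sampling distribution. Returns local chosen indices (-1 for
    censored trials) and decision times.
    """
    np.random.seed(seed)
    m, n = V.shape
    chosen = np.full(n_reps, -1, dtype=np.int64)
    times = np.full(n_reps, T_max, dtype=np.int64)
    X = np.empty(n)
    crossers = np.empty(n, dtype=np.int64)
    for r in range(n_reps):
        for i in range(n):
            X[i] = 0.0
        for t in range(1, T_max + 1):
            u = np.random.random()
            j = 0
            while cum_probs[j] <= u:
                j += 1
            total = 0.0
            for i in range(n):
                total += X[i]
            n_cross = 0
            for i in range(n):
                v = s_P * X[i] - l_P * (total - X[i]) + V[j, i]
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                X[i] = v
                if v >= Q:
                    crossers[n_cross] = i
                    n_cross += 1
            if n_cross > 0:
                if n_cross == 1:
                    chosen[r] = crossers[0]
                else:
                    chosen[r] = crossers[np.random.randint(n_cross)]
                times[r] = t
                break
    return chosen, times


def estimate_choice_probabilities(
    choice_set: ChoiceSet,
    params: NetworkParams,
    n_reps: int,
    rng: np.random.Generator,
    precomputed_inputs: np.ndarray | None = None,
) -> ChoiceProbabilities:
    """Empirical choice probabilities over ``n_reps`` independent decisions.

    Censored trials (no crossing by T_max) are resolved by a uniform random
    choice among the available alternatives so the probability vector stays
    normalized; the censoring rate is reported and logged.

    ``precomputed_inputs`` may carry the M x N weighted-equilibrium matrix
    from :func:`attribute_inputs` to share equilibria across calls.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if choice_set.n_considered == 0:
        raise ValueError("choice set has no available alternatives")
    if precomputed_inputs is None:
        V, _ = attribute_inputs(choice_set, params)
    else:
        V = precomputed_inputs
    cons = choice_set.considered_indices
    V_act = np.ascontiguousarray(V[:, cons])
    cum_probs = np.cumsum(params.attribute_probs(choice_set.n_attributes))
    cum_probs[-1] = 1.0  # guard against rounding in the sum
    seed = int(rng.integers(0, 2**31 - 1))
    local, times = _race_kernel(
        V_act, cum_probs, float(params.Q), int(params.T_max), int(n_reps),
        seed, float(params.s_P), float(params.l_P),
    )
    censored = local < 0
    n_cens = int(censored.sum())
    if n_cens:
        logger.info(
            "%d of %d simulated decisions censored at T_max=%d; resolved "
            "uniformly at random", n_cens, n_reps, params.T_max,
        )
        local[censored] = rng.integers(0, cons.size, size=n_cens)
    counts = np.bincount(cons[local], minlength=choice_set.n_alternatives)
    return ChoiceProbabilities(
        probabilities=counts / n_reps,
        mean_decision_time=float(times.mean()),
        censored_fraction=n_cens / n_reps,
        n_reps=n_reps,
    )
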