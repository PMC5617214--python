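"""Chinese restaurant franchise with finite capacity (CRFC).

Each restaurant (recording) holds at most ``N`` customers: once full, a new
segment can only be seated after the oldest one leaves, turning the franchise
into a sliding-window model whose seating rule uses the post-removal
(starred) counts with denominator ``N − 1 + alpha``.  Because that
denominator is common to every option, the categorical seating weights are
exactly those of the ordinary CRF evaluated on the starred counts, and the
warm-up phase (fewer than N customers) is the plain CRF.

``slide_and_track`` implements the real-time protocol: two class models are
initialized on the first 30-minute window of their training recordings, then
at each step every training restaurant drops its oldest segment and admits
the next one, a few Gibbs sweeps refresh the seating, and the test
recording's current window is scored to produce naive and quality-weighted
probabilities of the healthy class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import naive_probabilities, weighted_probabilities
from .hdpgmm import (
    Concentrations,
    FranchiseState,
    NIWPrior,
    SamplerSettings,
    TrainedModel,
    gibbs_sweep,
    log_predictive_segments,
    snapshot,
)


@dataclass
class WindowConfig:
    """Sliding-window sizes, in segments and minutes.

    ``capacity`` is the per-restaurant customer limit N = M_win×60/l;
    the analysis covers ``analysis_minutes`` of signal, so the tracker emits
    (analysis − window) minutes' worth of steps.
    """

    capacity: int
    window_minutes: float = 30.0
    analysis_minutes: float = 45.0
    sweeps_per_step: int = 5

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be positive")
        if self.analysis_minutes < self.window_minutes:
            raise ValueError("analysis window shorter than sliding window")

    def n_analysis_segments(self) -> int:
        return int(round(self.capacity * self.analysis_minutes
                         / self.window_minutes))


def remove_oldest(state: FranchiseState, j: str) -> tuple[int, np.ndarray]:
    """Evict restaurant ``j``'s oldest customer, pruning emptied tables and
    dishes; returns the customer id and its observation."""
    rest = state.restaurants[j]
    if not rest.order:
        raise ValueError("empty restaurant")
    cid = rest.order.pop(0)
    x = state.detach(j, cid)
    del rest.customers[cid]
    return cid, x


def add_customer_finite(
    state: FranchiseState, j: str, x: np.ndarray, conc: Concentrations,
    rng: np.random.Generator, capacity: int,
) -> int:
    """Seat a new customer under the finite-capacity rule.

    The caller must have evicted the oldest customer first when at capacity;
    on the starred counts the seating weights coincide with the CRF's, so the
    shared seating routine applies.
    """
    if state.n_customers(j) >= capacity:
        raise ValueError("restaurant at capacity; remove the oldest first")
    return state.seat_customer(j, x, conc, rng)


def slide_and_track(
    test_segments: np.ndarray,
    test_u: np.ndarray,
    train_healthy: list[np.ndarray],
    train_unhealthy: list[np.ndarray],
    cfg: WindowConfig,
    prior: NIWPrior | None = None,
    conc: Concentrations | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Track class probabilities of a test recording over time.

    All recordings are (T × q) arrays of reduced features with
    T = analysis segments; the test quality vector aligns with its segments.
    Returns an array of rows (step, p0, p1, p0_weighted, p1_weighted).
    """
    T = cfg.n_analysis_segments()
    N = cfg.capacity
    test_segments = np.atleast_2d(np.asarray(test_segments, dtype=float))
    if test_segments.shape[0] < T:
        raise ValueError("recording too short")
    for name, group in (("healthy", train_healthy),
                        ("unhealthy", train_unhealthy)):
        for g in group:
            if np.atleast_2d(g).shape[0] < T:
                raise ValueError(f"{name} training recording too short")

    if prior is None:
        X_all = np.vstack([np.atleast_2d(g) for g in
                           train_healthy + train_unhealthy])
        prior = NIWPrior.from_data(X_all)
    conc = conc or Concentrations()
    rng = np.random.default_rng(seed)

    states: dict[str, FranchiseState] = {}
    concs: dict[str, Concentrations] = {}
    groups = {"healthy": train_healthy, "unhealthy": train_unhealthy}
    for label, recs in groups.items():
        st = FranchiseState(prior)
        for r, rec in enumerate(recs):
            st.add_restaurant(f"r{r}")
            for x in np.atleast_2d(rec)[:N]:
                st.seat_customer(f"r{r}", x, conc, rng)
        c = conc
        for _ in range(cfg.sweeps_per_step):
            c = gibbs_sweep(st, c, rng)
        states[label], concs[label] = st, c

    rows = []
    for step in range(T - N + 1):
        if step > 0:
            for label, recs in groups.items():
                st = states[label]
                for r, rec in enumerate(recs):
                    remove_oldest(st, f"r{r}")
                    add_customer_finite(st, f"r{r}",
                                        np.atleast_2d(rec)[N - 1 + step],
                                        concs[label], rng, N)
                for _ in range(cfg.sweeps_per_step):
                    concs[label] = gibbs_sweep(st, concs[label], rng)

        window = slice(step, step + N)
        Xw = test_segments[window]
        uw = np.asarray(test_u, dtype=float)[window]
        scores = {}
        for label in ("healthy", "unhealthy"):
            model = TrainedModel(
                states=[snapshot(states[label], concs[label])],
                prior=prior, settings=SamplerSettings(1, 0, 1), seed=seed)
            scores[label] = log_predictive_segments(Xw, model)
        l0_i, l1_i = scores["healthy"], scores["unhealthy"]
        p0, p1 = naive_probabilities(float(l0_i.sum()), float(l1_i.sum()),
                                     m=N)
        p0w, p1w = weighted_probabilities(l0_i, l1_i, uw)
        rows.append((step, p0, p1, p0w, p1w))
    return np.array(rows)
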