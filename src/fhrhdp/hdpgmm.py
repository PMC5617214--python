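"""Hierarchical Dirichlet process Gaussian mixtures via the Chinese restaurant
franchise, with collapsed Gibbs inference.

Observations (PCA-reduced segment feature vectors) are grouped by recording.
In the franchise metaphor each recording is a restaurant, each observation a
customer choosing a table within its restaurant, and each table is served a
dish — a global Gaussian mixture component shared across all recordings.
The Gaussian components carry a conjugate Normal–Inverse–Wishart (NIW) base
measure, so component parameters are integrated out and the sampler works
only with seating indicators: per-customer tables ``t_ji`` and per-table
dishes ``k_jt``.  Customers join an occupied table with probability
proportional to its occupancy times the dish's leave-one-out posterior
predictive, or open a new table with probability proportional to the
concentration ``alpha`` times the franchise-level predictive mixture; tables
pick dishes proportionally to the global table count ``m_k`` times the
dish's leave-block-out predictive, or a new dish via ``gamma``.
Both concentrations carry gamma hyperpriors and are resampled by
auxiliary-variable schemes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Conjugate base measure and component sufficient statistics

@dataclass
class NIWPrior:
    """Normal–Inverse–Wishart base measure H over (mean, covariance).

    ``mu0`` prior mean, ``kappa0`` prior mean-strength (pseudo-counts),
    ``nu0`` inverse-Wishart degrees of freedom (> q−1), ``psi0`` its scatter
    matrix (q × q, symmetric positive definite).
    """

    mu0: np.ndarray
    kappa0: float
    nu0: float
    psi0: np.ndarray

    def __post_init__(self) -> None:
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.psi0 = np.atleast_2d(np.asarray(self.psi0, dtype=float))
        q = self.mu0.size
        if self.psi0.shape != (q, q):
            raise ValueError("psi0 must be q x q")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.nu0 <= q - 1:
            raise ValueError("nu0 must exceed q - 1")
        if not np.allclose(self.psi0, self.psi0.T):
            raise ValueError("psi0 must be symmetric")
        if np.any(np.linalg.eigvalsh(self.psi0) <= 0):
            raise ValueError("psi0 must be positive definite")

    @property
    def q(self) -> int:
        return self.mu0.size

    @staticmethod
    def from_data(X: np.ndarray, kappa0: float = 0.01) -> "NIWPrior":
        """Weakly-informative data-scaled default: mu0 = data mean,
        nu0 = q + 2, psi0 = empirical covariance."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        q = X.shape[1]
        cov = np.cov(X, rowvar=False).reshape(q, q)
        cov += 1e-8 * np.eye(q) * max(np.trace(cov) / q, 1.0)
        return NIWPrior(mu0=X.mean(axis=0), kappa0=kappa0, nu0=q + 2.0, psi0=cov)


class GaussianComponentStats:
    """Streaming sufficient statistics of one dish: n, Σx, Σxxᵀ."""

    __slots__ = ("q", "n", "sum", "sumsq", "_version", "_cache_version", "_cache")

    def __init__(self, q: int):
        self.q = q
        self.n = 0
        self.sum = np.zeros(q)
        self.sumsq = np.zeros((q, q))
        self._version = 0
        self._cache_version = -1
        self._cache = None

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        self.sum += x
        self.sumsq += np.outer(x, x)
        self._version += 1

    def remove(self, x: np.ndarray) -> None:
        if self.n <= 0:
            raise ValueError("cannot remove from empty component")
        self.n -= 1
        self.sum -= x
        self.sumsq -= np.outer(x, x)
        self._version += 1

    def copy(self) -> "GaussianComponentStats":
        out = GaussianComponentStats(self.q)
        out.n = self.n
        out.sum = self.sum.copy()
        out.sumsq = self.sumsq.copy()
        return out


def _posterior_params(stats: GaussianComponentStats | None, prior: NIWPrior):
    """NIW posterior (mu_n, kappa_n, nu_n, psi_n) given component stats."""
    if stats is None or stats.n == 0:
        return prior.mu0, prior.kappa0, prior.nu0, prior.psi0
    n = stats.n
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    mu_n = (prior.kappa0 * prior.mu0 + stats.sum) / kappa_n
    xbar = stats.sum / n
    S = stats.sumsq - np.outer(stats.sum, xbar)
    d = xbar - prior.mu0
    psi_n = prior.psi0 + S + (prior.kappa0 * n / kappa_n) * np.outer(d, d)
    return mu_n, kappa_n, nu_n, psi_n


def _predictive_cache(stats: GaussianComponentStats | None, prior: NIWPrior):
    """Student-t parameters of the posterior predictive, cached per version."""
    if stats is not None and stats._cache_version == stats._version:
        return stats._cache
    mu_n, kappa_n, nu_n, psi_n = _posterior_params(stats, prior)
    q = prior.q
    df = nu_n - q + 1.0
    scale = psi_n * ((kappa_n + 1.0) / (kappa_n * df))
    try:
        chol = np.linalg.cholesky(scale)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-positive-definite posterior scatter") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    const = (gammaln((df + q) / 2.0) - gammaln(df / 2.0)
             - 0.5 * q * math.log(df * math.pi) - 0.5 * logdet)
    cache = (mu_n, chol, df, const, q)
    if stats is not None:
        stats._cache = cache
        stats._cache_version = stats._version
    return cache


def _student_t_logpdf(x: np.ndarray, cache) -> float:
    mu, chol, df, const, q = cache
    z = np.linalg.solve(chol, x - mu) if q > 1 else (x - mu) / chol[0, 0]
    quad = float(z @ z) if q > 1 else float(z[0] * z[0])
    return const - 0.5 * (df + q) * math.log1p(quad / df)


def log_posterior_predictive(
    x: np.ndarray,
    stats: GaussianComponentStats | None,
    prior: NIWPrior,
    exclude: np.ndarray | None = None,
) -> float:
    """Log leave-one-out posterior predictive density of ``x`` for one dish.

    This is the collapsed-likelihood term f_k^{-x}(x): a multivariate
    Student-t implied by the NIW posterior of the component's remaining
    observations.  With empty stats it reduces to the prior predictive.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != prior.q:
        raise ValueError("dimension mismatch")
    if exclude is not None:
        if stats is None or stats.n == 0:
            raise ValueError("cannot exclude from empty component")
        stats = stats.copy()
        stats.remove(np.atleast_1d(np.asarray(exclude, dtype=float)))
    return _student_t_logpdf(x, _predictive_cache(stats, prior))


def log_prior_predictive(x: np.ndarray, prior: NIWPrior) -> float:
    """Log density of ``x`` under the NIW prior predictive (Student-t)."""
    return log_posterior_predictive(x, None, prior)


def log_block_predictive(
    X: np.ndarray, stats: GaussianComponentStats | None, prior: NIWPrior
) -> float:
    """Joint predictive of a block of observations given a dish's stats.

    Chain rule: f(x1)·f(x2|x1)·…, each factor the Student-t posterior
    predictive with the previous block members temporarily absorbed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    work = stats.copy() if stats is not None else GaussianComponentStats(prior.q)
    total = 0.0
    for x in X:
        total += _student_t_logpdf(x, _predictive_cache(work, prior))
        work.add(x)
    return total


# ---------------------------------------------------------------------------
# Concentration parameters

@dataclass
class Concentrations:
    """DP concentrations with gamma hyperpriors (shape, rate)."""

    alpha: float = 10.0
    gamma: float = 1.0
    alpha_prior: tuple[float, float] = (10.0, 1.0)
    gamma_prior: tuple[float, float] = (1.0, 1.0)
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("concentrations must be positive")


def sample_gamma_concentration(
    gamma: float, K: int, m_total: int, prior: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """One Escobar–West auxiliary-variable update of the top-level
    concentration given K live dishes among m_total tables."""
    a, b = prior
    if m_total == 0:
        return float(rng.gamma(a, 1.0 / b))
    eta = rng.beta(gamma + 1.0, m_total)
    odds = (a + K - 1.0) / (m_total * (b - math.log(eta)))
    shape = a + K if rng.random() < odds / (1.0 + odds) else a + K - 1.0
    return float(rng.gamma(shape, 1.0 / (b - math.log(eta))))


def sample_alpha_concentration(
    alpha: float, n_per_restaurant: list[int], total_tables: int,
    prior: tuple[float, float], rng: np.random.Generator,
) -> float:
    """One auxiliary-variable update of the restaurant-level concentration
    shared across groups (Teh et al.'s scheme): per restaurant draw
    w_j ~ Beta(alpha+1, n_j) and s_j ~ Bernoulli(n_j/(n_j+alpha)), then
    alpha ~ Gamma(a + m·· − Σ s_j, b − Σ log w_j)."""
    a, b = prior
    n_per_restaurant = [n for n in n_per_restaurant if n > 0]
    if not n_per_restaurant:
        return float(rng.gamma(a, 1.0 / b))
    log_w = 0.0
    s_total = 0
    for n_j in n_per_restaurant:
        log_w += math.log(rng.beta(alpha + 1.0, n_j))
        s_total += int(rng.random() < n_j / (n_j + alpha))
    return float(rng.gamma(a + total_tables - s_total, 1.0 / (b - log_w)))


# ---------------------------------------------------------------------------
# Franchise bookkeeping

@dataclass
class _Table:
    dish: int
    customers: set


@dataclass
class _Restaurant:
    tables: dict = field(default_factory=dict)          # table_id -> _Table
    customers: dict = field(default_factory=dict)       # cid -> x vector
    assignment: dict = field(default_factory=dict)      # cid -> table_id
    order: list = field(default_factory=list)           # cids in arrival order


@dataclass
class _Dish:
    stats: GaussianComponentStats
    m: int = 0   # tables serving this dish across the franchise


def categorical_from_logweights(logw: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index from unnormalized log weights (log-sum-exp stabilized)."""
    logw = np.asarray(logw, dtype=float)
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


def seating_probabilities(
    table_counts: np.ndarray, table_logliks: np.ndarray,
    alpha: float, log_new_table_lik: float,
) -> np.ndarray:
    """Normalized table-choice probabilities: occupied tables get weight
    n_jt·f_k(x); a new table gets alpha·p(x|t_new).  Last entry = new table."""
    logw = np.concatenate([
        np.log(np.asarray(table_counts, dtype=float)) + np.asarray(table_logliks),
        [math.log(alpha) + log_new_table_lik],
    ])
    w = np.exp(logw - logw.max())
    return w / w.sum()


def dish_probabilities(
    m_counts: np.ndarray, dish_logliks: np.ndarray,
    gamma: float, log_new_dish_lik: float,
) -> np.ndarray:
    """Normalized dish-choice probabilities: existing dishes get m_k·f_k(·);
    a new dish gets gamma·(prior predictive).  Last entry = new dish."""
    logw = np.concatenate([
        np.log(np.asarray(m_counts, dtype=float)) + np.asarray(dish_logliks),
        [math.log(gamma) + log_new_dish_lik],
    ])
    w = np.exp(logw - logw.max())
    return w / w.sum()


class FranchiseState:
    """Full CRF bookkeeping: seating, dish assignments, counts and stats."""

    def __init__(self, prior: NIWPrior):
        self.prior = prior
        self.restaurants: dict[str, _Restaurant] = {}
        self.dishes: dict[int, _Dish] = {}
        self._next_table = 0
        self._next_dish = 0
        self._next_cid = 0

    # -- queries ------------------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.dishes)

    @property
    def total_tables(self) -> int:
        return sum(d.m for d in self.dishes.values())

    def n_customers(self, j: str) -> int:
        return len(self.restaurants[j].customers)

    # -- structural updates --------------------------------------------------

    def add_restaurant(self, j: str) -> None:
        if j in self.restaurants:
            raise ValueError(f"restaurant {j!r} already exists")
        self.restaurants[j] = _Restaurant()

    def _new_dish(self) -> int:
        k = self._next_dish
        self._next_dish += 1
        self.dishes[k] = _Dish(stats=GaussianComponentStats(self.prior.q))
        return k

    def _attach(self, j: str, cid: int, x: np.ndarray, table_id: int) -> None:
        rest = self.restaurants[j]
        table = rest.tables[table_id]
        table.customers.add(cid)
        rest.assignment[cid] = table_id
        self.dishes[table.dish].stats.add(x)

    def _open_table(self, j: str, dish: int) -> int:
        t = self._next_table
        self._next_table += 1
        self.restaurants[j].tables[t] = _Table(dish=dish, customers=set())
        self.dishes[dish].m += 1
        return t

    def _close_table_if_empty(self, j: str, table_id: int) -> None:
        rest = self.restaurants[j]
        table = rest.tables[table_id]
        if table.customers:
            return
        del rest.tables[table_id]
        dish = self.dishes[table.dish]
        dish.m -= 1
        if dish.m == 0:
            del self.dishes[table.dish]

    def detach(self, j: str, cid: int) -> np.ndarray:
        """Remove customer ``cid`` from its table (leave-one-out counts)."""
        rest = self.restaurants[j]
        x = rest.customers[cid]
        table_id = rest.assignment.pop(cid)
        table = rest.tables[table_id]
        table.customers.discard(cid)
        self.dishes[table.dish].stats.remove(x)
        self._close_table_if_empty(j, table_id)
        return x

    # -- collapsed Gibbs moves ----------------------------------------------

    def _dish_choice(self, x: np.ndarray, conc: Concentrations,
                     dish_logliks: dict[int, float]):
        dish_ids = list(self.dishes.keys())
        m_counts = np.array([self.dishes[k].m for k in dish_ids], dtype=float)
        logliks = np.array([dish_logliks[k] for k in dish_ids])
        log_prior_pred = log_prior_predictive(x, self.prior)
        return dish_ids, m_counts, logliks, log_prior_pred

    def seat_customer(
        self, j: str, x: np.ndarray, conc: Concentrations,
        rng: np.random.Generator, cid: int | None = None,
    ) -> int:
        """Seat one (detached or brand-new) customer by the collapsed rule.

        Occupied tables are weighted by occupancy times the dish's posterior
        predictive; a new table by alpha times the franchise predictive
        mixture.  If a new table opens, its dish is drawn the same way from
        table counts m_k versus gamma.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        rest = self.restaurants[j]
        if cid is None:
            cid = self._next_cid
            self._next_cid += 1
            rest.customers[cid] = x
            rest.order.append(cid)

        dish_logliks = {
            k: log_posterior_predictive(x, d.stats, self.prior)
            for k, d in self.dishes.items()
        }
        dish_ids, m_counts, logliks, log_prior_pred = self._dish_choice(
            x, conc, dish_logliks)

        if dish_ids:
            mix_logw = np.concatenate([
                np.log(m_counts) + logliks,
                [math.log(conc.gamma) + log_prior_pred],
            ])
        else:
            mix_logw = np.array([math.log(conc.gamma) + log_prior_pred])
        lse = float(np.logaddexp.reduce(mix_logw))
        log_new_table_lik = lse - math.log(self.total_tables + conc.gamma)

        table_ids = list(rest.tables.keys())
        counts = np.array([len(rest.tables[t].customers) for t in table_ids],
                          dtype=float)
        tbl_logliks = np.array([dish_logliks[rest.tables[t].dish]
                                for t in table_ids])
        probs = seating_probabilities(counts, tbl_logliks, conc.alpha,
                                      log_new_table_lik) if table_ids else \
            np.array([1.0])
        assert abs(probs.sum() - 1.0) < 1e-9
        cdf = np.cumsum(probs)
        choice = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))

        if choice < len(table_ids):
            self._attach(j, cid, x, table_ids[choice])
            return cid

        # new table: draw its dish from m_k·f_k vs gamma·prior
        dish_probs = np.exp(mix_logw - mix_logw.max())
        dish_probs /= dish_probs.sum()
        dcdf = np.cumsum(dish_probs)
        dchoice = int(np.searchsorted(dcdf, rng.random() * dcdf[-1], side="right"))
        dish = dish_ids[dchoice] if dchoice < len(dish_ids) else self._new_dish()
        table_id = self._open_table(j, dish)
        self._attach(j, cid, x, table_id)
        return cid

    def resample_table(self, j: str, cid: int, conc: Concentrations,
                       rng: np.random.Generator) -> None:
        self.detach(j, cid)
        self.seat_customer(j, self.restaurants[j].customers[cid], conc, rng,
                           cid=cid)

    def resample_dish(self, j: str, table_id: int, conc: Concentrations,
                      rng: np.random.Generator) -> None:
        """Resample the dish of one table given its whole customer block."""
        rest = self.restaurants[j]
        if table_id not in rest.tables:
            raise ValueError("unoccupied table")
        table = rest.tables[table_id]
        X = np.array([rest.customers[c] for c in sorted(table.customers)])
        old_dish = table.dish
        # detach the block from its dish
        dish = self.dishes[old_dish]
        for x in X:
            dish.stats.remove(x)
        dish.m -= 1
        if dish.m == 0:
            assert dish.stats.n == 0
            del self.dishes[old_dish]

        dish_ids = list(self.dishes.keys())
        m_counts = np.array([self.dishes[k].m for k in dish_ids], dtype=float)
        logliks = np.array([
            log_block_predictive(X, self.dishes[k].stats, self.prior)
            for k in dish_ids
        ])
        log_new = log_block_predictive(X, None, self.prior)
        probs = dish_probabilities(m_counts, logliks, conc.gamma, log_new) \
            if dish_ids else np.array([1.0])
        assert abs(probs.sum() - 1.0) < 1e-9
        cdf = np.cumsum(probs)
        choice = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
        new_dish = dish_ids[choice] if choice < len(dish_ids) else self._new_dish()

        table.dish = new_dish
        self.dishes[new_dish].m += 1
        for x in X:
            self.dishes[new_dish].stats.add(x)

    # -- integrity ----------------------------------------------------------

    def check_invariants(self) -> None:
        total_tables = 0
        for j, rest in self.restaurants.items():
            seated = set()
            for t, table in rest.tables.items():
                if not table.customers:
                    raise AssertionError(f"empty table {t} in {j}")
                if table.dish not in self.dishes:
                    raise AssertionError(f"dangling dish on table {t}")
                seated |= table.customers
            if seated != set(rest.assignment.keys()) or \
                    seated != set(rest.customers.keys()):
                raise AssertionError(f"customer bookkeeping broken in {j}")
            total_tables += len(rest.tables)
        if total_tables != self.total_tables:
            raise AssertionError("table count marginals inconsistent")
        for k, dish in self.dishes.items():
            if dish.m < 1:
                raise AssertionError(f"dead dish {k} retained")
            n_k = sum(
                len(t.customers)
                for rest in self.restaurants.values()
                for t in rest.tables.values() if t.dish == k
            )
            if n_k != dish.stats.n:
                raise AssertionError(f"stats count mismatch for dish {k}")


# ---------------------------------------------------------------------------
# Fitting and prediction

@dataclass
class SamplerSettings:
    iterations: int = 1000
    burn_in: int = 500
    thin: int = 5
    freeze_concentrations: bool = False

    def __post_init__(self) -> None:
        if self.iterations < self.burn_in:
            raise ValueError("iterations must cover burn-in")


@dataclass
class PosteriorState:
    """One retained snapshot: per-dish stats, table counts, concentrations."""

    dish_stats: list[GaussianComponentStats]
    m_counts: np.ndarray
    alpha: float
    gamma: float


@dataclass
class TrainedModel:
    states: list[PosteriorState]
    prior: NIWPrior
    settings: SamplerSettings
    seed: int


def snapshot(state: FranchiseState, conc: Concentrations) -> PosteriorState:
    ids = sorted(state.dishes.keys())
    return PosteriorState(
        dish_stats=[state.dishes[k].stats.copy() for k in ids],
        m_counts=np.array([state.dishes[k].m for k in ids], dtype=float),
        alpha=conc.alpha,
        gamma=conc.gamma,
    )


def gibbs_sweep(
    state: FranchiseState, conc: Concentrations, rng: np.random.Generator,
) -> Concentrations:
    """One full sweep: every t_ji, then every k_jt, then the concentrations."""
    for j in sorted(state.restaurants.keys()):
        for cid in sorted(state.restaurants[j].customers.keys()):
            state.resample_table(j, cid, conc, rng)
    for j in sorted(state.restaurants.keys()):
        for table_id in sorted(state.restaurants[j].tables.keys()):
            if table_id in state.restaurants[j].tables:
                state.resample_dish(j, table_id, conc, rng)
    return sample_concentrations(state, conc, rng)


def sample_concentrations(
    state: FranchiseState, conc: Concentrations, rng: np.random.Generator,
) -> Concentrations:
    if conc.frozen:
        return conc
    gamma = sample_gamma_concentration(
        conc.gamma, state.K, state.total_tables, conc.gamma_prior, rng)
    n_js = [state.n_customers(j) for j in sorted(state.restaurants.keys())]
    alpha = sample_alpha_concentration(
        conc.alpha, n_js, state.total_tables, conc.alpha_prior, rng)
    return replace(conc, alpha=alpha, gamma=gamma)


def initialize_state(
    groups: dict[str, np.ndarray], prior: NIWPrior, conc: Concentrations,
    rng: np.random.Generator,
) -> FranchiseState:
    """Sequential CRF initialization: customers seated one by one by the
    prior-times-likelihood rule (a valid draw from the model)."""
    state = FranchiseState(prior)
    for j in sorted(groups.keys()):
        state.add_restaurant(j)
        for x in np.atleast_2d(groups[j]):
            state.seat_customer(j, x, conc, rng)
    return state


def fit_hdpgm(
    groups: dict[str, np.ndarray],
    prior: NIWPrior | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    conc: Concentrations | None = None,
    callback=None,
) -> TrainedModel:
    """Fit one HDP Gaussian mixture to grouped data by collapsed Gibbs.

    ``groups`` maps recording id -> (m_j × q) array of reduced feature
    vectors.  Retains thinned post-burn-in posterior snapshots.
    """
    if not groups:
        raise ValueError("no data")
    settings = settings or SamplerSettings()
    X_all = np.vstack([np.atleast_2d(g) for g in groups.values()])
    prior = prior or NIWPrior.from_data(X_all)
    conc = conc or Concentrations()
    rng = np.random.default_rng(seed)
    state = initialize_state(groups, prior, conc, rng)
    retained: list[PosteriorState] = []
    for it in range(settings.iterations):
        conc = gibbs_sweep(state, conc, rng)
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            retained.append(snapshot(state, conc))
        if callback is not None:
            callback(it, state, conc)
    if not retained:
        retained.append(snapshot(state, conc))
    return TrainedModel(states=retained, prior=prior, settings=settings,
                        seed=seed)


def _log_density_state(x: np.ndarray, ps: PosteriorState, prior: NIWPrior) -> float:
    """Mixture density of one snapshot: dishes weighted by table counts plus
    the gamma-weighted new-dish (prior predictive) mass — a test segment is
    treated as a new table's first customer."""
    logw = [
        math.log(m) + log_posterior_predictive(x, st, prior)
        for st, m in zip(ps.dish_stats, ps.m_counts)
    ]
    logw.append(math.log(ps.gamma) + log_prior_predictive(x, prior))
    m_total = float(ps.m_counts.sum())
    return float(np.logaddexp.reduce(logw)) - math.log(m_total + ps.gamma)


def log_predictive_segments(X: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Per-segment predictive log density, density-averaged over snapshots."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.prior.q:
        raise ValueError("dimension mismatch")
    S = len(model.states)
    per_state = np.empty((S, X.shape[0]))
    for s, ps in enumerate(model.states):
        per_state[s] = [_log_density_state(x, ps, model.prior) for x in X]
    return np.logaddexp.reduce(per_state, axis=0) - math.log(S)


def log_predictive_recording(
    X: np.ndarray, model: TrainedModel
) -> tuple[float, np.ndarray]:
    """Total and per-segment log-likelihood of a recording under the model."""
    per_segment = log_predictive_segments(X, model)
    return float(per_segment.sum()), per_segment


# ---------------------------------------------------------------------------
# Serialization

def model_to_json(model: TrainedModel) -> str:
    return json.dumps({
        "prior": {
            "mu0": model.prior.mu0.tolist(),
            "kappa0": model.prior.kappa0,
            "nu0": model.prior.nu0,
            "psi0": model.prior.psi0.tolist(),
        },
        "settings": {
            "iterations": model.settings.iterations,
            "burn_in": model.settings.burn_in,
            "thin": model.settings.thin,
            "freeze_concentrations": model.settings.freeze_concentrations,
        },
        "seed": model.seed,
        "states": [
            {
                "alpha": ps.alpha,
                "gamma": ps.gamma,
                "m_counts": ps.m_counts.tolist(),
                "dishes": [
                    {"n": st.n, "sum": st.sum.tolist(),
                     "sumsq": st.sumsq.tolist()}
                    for st in ps.dish_stats
                ],
            }
            for ps in model.states
        ],
    })


def model_from_json(doc: str) -> TrainedModel:
    d = json.loads(doc)
    prior = NIWPrior(
        mu0=np.array(d["prior"]["mu0"]), kappa0=d["prior"]["kappa0"],
        nu0=d["prior"]["nu0"], psi0=np.array(d["prior"]["psi0"]))
    settings = SamplerSettings(**d["settings"])
    states = []
    for s in d["states"]:
        dish_stats = []
        for dd in s["dishes"]:
            st = GaussianComponentStats(prior.q)
            st.n = int(dd["n"])
            st.sum = np.array(dd["sum"], dtype=float)
            st.sumsq = np.array(dd["sumsq"], dtype=float)
            dish_stats.append(st)
        states.append(PosteriorState(
            dish_stats=dish_stats, m_counts=np.array(s["m_counts"]),
            alpha=s["alpha"], gamma=s["gamma"]))
    return TrainedModel(states=states, prior=prior, settings=settings,
                        seed=int(d["seed"]))
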