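"""Simulation scenarios for benchmarking Q-matrix correlations.

Three designs bracket the correlation between Rasch item difficulties and
LLTM-reconstructed difficulties:

* **Scenario 1 — random Q-matrices (lower benchmark).**  Binary weight
  matrices with entries drawn independently (probability ``prop_ones``) are
  fitted to a fixed dataset; the resulting correlations show how well a
  purely haphazard cognitive model can do.
* **Scenario 2 — row-perturbed Q-matrices (graded benchmark).**  Random row
  permutations of a theoretical Q-matrix (identity excluded), classified by
  how many rows are displaced (small / medium / large), interpolate between
  the theoretical matrix and full randomness.
* **Scenario 3 — LLTM-generated data (upper benchmark).**  Datasets are
  simulated from the LLTM itself, so the Q-matrix is correct by construction;
  refitting both models per dataset shows the best correlation one can expect
  given sampling error, and the LR rejection rate estimates the type-I risk.

Replicates whose LLTM fit fails (rank-deficient Q, estimation failure, or no
convergence within budget) are recorded and excluded from the summaries, with
counts reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .comparison import ComparisonResult, lr_test
from .data import ResponseMatrix, WeightMatrix
from .estimation import fit_lltm, fit_rasch, reconstruct_item_parameters
from .exceptions import EstimationError, ValidationError
from .validate import item_parameter_correlation

__all__ = [
    "ScenarioConfig",
    "PerturbedQ",
    "ReplicateRecord",
    "NullCorrelationDistribution",
    "simulate_random_q",
    "sample_row_permutations",
    "simulate_rasch_data",
    "simulate_lltm_data",
    "spread_difficulties",
    "synthetic_qmatrix",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
]

# Displacement-count cut-offs (small_max, medium_max) for the two test
# lengths studied in the source designs; other lengths fall back to terciles.
_SIZE_CLASS_CUTOFFS = {23: (7, 15), 17: (6, 12)}


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of a simulation run.

    Parameters
    ----------
    scenario : 1, 2 or 3.
    reps : number of replicates (1,000 in the reference design).
    prop_ones : probability that a random Q entry is 1 (Scenario 1); ``None``
        means "match the theoretical Q-matrix density" where a caller
        resolves it.
    seed : RNG seed; every run is bit-reproducible given (seed, config).
    alpha : LR-test significance level.
    persons, theta_mean, theta_sd : synthetic-data generator settings
        (Scenario 3 and the stand-in datasets).
    exact_quota : if True, random Q-matrices contain an exact count of ones
        instead of independent Bernoulli entries.
    correlation : "pearson" (default) or "spearman".
    tol, max_iter : CML convergence settings passed to the fitters.
    """

    scenario: int = 1
    reps: int = 1000
    prop_ones: float | None = 0.5
    seed: int = 0
    alpha: float = 0.05
    persons: int = 300
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    exact_quota: bool = False
    correlation: str = "pearson"
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValidationError("scenario must be 1, 2 or 3")
        if self.reps < 1:
            raise ValidationError("reps must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.prop_ones is not None and not (0.0 < self.prop_ones < 1.0):
            raise ValidationError("prop_ones must be in (0, 1)")
        if self.persons < 1:
            raise ValidationError("persons must be at least 1")
        if self.theta_sd <= 0:
            raise ValidationError("theta_sd must be positive")
        if self.correlation not in ("pearson", "spearman"):
            raise ValidationError("correlation must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class PerturbedQ:
    """A row-permuted weight matrix with its displacement bookkeeping."""

    Q_perturbed: WeightMatrix
    permutation: np.ndarray
    n_misplaced: int
    size_class: str


@dataclass(frozen=True)
class ReplicateRecord:
    """Per-replicate outcome of one simulated weight matrix or dataset."""

    replicate: int
    converged: bool
    r: float = float("nan")
    lr_statistic: float = float("nan")
    lr_df: int = 0
    lr_p: float = float("nan")
    aic_rm: float = float("nan")
    bic_rm: float = float("nan")
    aic_lltm: float = float("nan")
    bic_lltm: float = float("nan")
    n_misplaced: int | None = None
    size_class: str | None = None


@dataclass
class NullCorrelationDistribution:
    """Replicate correlations and model-comparison bookkeeping of a scenario run."""

    scenario: int
    config: ScenarioConfig
    records: list[ReplicateRecord] = field(default_factory=list)

    @property
    def n_requested(self) -> int:
        return len(self.records)

    @property
    def n_converged(self) -> int:
        return sum(rec.converged for rec in self.records)

    @property
    def correlations(self) -> np.ndarray:
        """Correlations of converged replicates only."""
        return np.array([rec.r for rec in self.records if rec.converged])

    def summary(self) -> dict:
        """Min, 5th percentile, quartiles, median, mean, 95th percentile, max."""
        r = self.correlations
        if r.size == 0:
            keys = ("min", "p5", "q1", "median", "mean", "q3", "p95", "max")
            return {k: float("nan") for k in keys} | {"n": 0}
        q = np.percentile(r, [5, 25, 50, 75, 95])  # linear interpolation
        return {
            "min": float(r.min()),
            "p5": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "mean": float(r.mean()),
            "q3": float(q[3]),
            "p95": float(q[4]),
            "max": float(r.max()),
            "n": int(r.size),
        }

    def ic_summary(self) -> dict:
        """LLTM AIC/BIC spread and percent of replicates favoring the LLTM."""
        out: dict = {}
        conv = [rec for rec in self.records if rec.converged]
        for name, rm_attr, lltm_attr in (
            ("aic", "aic_rm", "aic_lltm"),
            ("bic", "bic_rm", "bic_lltm"),
        ):
            lltm_vals = np.array([getattr(rec, lltm_attr) for rec in conv])
            rm_vals = np.array([getattr(rec, rm_attr) for rec in conv])
            if lltm_vals.size == 0:
                out[name] = {
                    "min": float("nan"),
                    "mean": float("nan"),
                    "max": float("nan"),
                    "percent_favor_lltm": float("nan"),
                }
                continue
            out[name] = {
                "min": float(lltm_vals.min()),
                "mean": float(lltm_vals.mean()),
                "max": float(lltm_vals.max()),
                "percent_favor_lltm": float(100.0 * np.mean(lltm_vals < rm_vals)),
            }
        return out

    @property
    def lr_reject_rate(self) -> float:
        """Fraction of converged replicates with LR p-value below alpha."""
        ps = np.array([rec.lr_p for rec in self.records if rec.converged])
        if ps.size == 0:
            return float("nan")
        return float(np.mean(ps < self.config.alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(rec) for rec in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "config": asdict(self.config),
            "n_requested": self.n_requested,
            "n_converged": self.n_converged,
            "correlations": self.summary(),
            "information_criteria": self.ic_summary(),
            "lr_reject_rate": self.lr_reject_rate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def spread_difficulties(k: int, low: float = -2.0, high: float = 2.0) -> np.ndarray:
    """Evenly spread item difficulties, the stand-in for a real test."""
    if k < 2:
        raise ValidationError("at least two items are required")
    return np.linspace(low, high, k)


def simulate_random_q(
    k: int,
    p: int,
    prop_ones: float,
    rng: np.random.Generator,
    exact_quota: bool = False,
) -> WeightMatrix:
    """Draw a random binary weight matrix.

    Entries are independent Bernoulli(``prop_ones``) by default; with
    ``exact_quota=True`` the matrix contains exactly ``round(prop_ones*k*p)``
    ones placed uniformly at random.  Rank-deficient draws are returned
    as-is with :attr:`WeightMatrix.is_identifiable` False — callers decide
    whether to book them as non-convergent.
    """
    if k < 2 or not (1 <= p < k):
        raise ValidationError("need k >= 2 and 1 <= p < k")
    if not (0.0 <= prop_ones <= 1.0):
        raise ValidationError("prop_ones must be in [0, 1]")
    if exact_quota:
        n_ones = int(round(prop_ones * k * p))
        flat = np.zeros(k * p, dtype=np.int64)
        flat[rng.choice(k * p, size=n_ones, replace=False)] = 1
        W = flat.reshape(k, p)
    else:
        W = (rng.random((k, p)) < prop_ones).astype(np.int64)
    return WeightMatrix(weights=W)


def synthetic_qmatrix(
    k: int, p: int, prop_ones: float = 0.38, seed: int = 12345
) -> WeightMatrix:
    """A fixed, identifiable binary Q-matrix standing in for a theoretical one.

    Deterministic given (k, p, prop_ones, seed); re-drawn until ``[Q | 1]``
    has full column rank and no operation column is constant.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        Q = simulate_random_q(k, p, prop_ones, rng)
        col_ok = np.all((Q.weights.sum(axis=0) > 0) & (Q.weights.sum(axis=0) < k))
        if Q.is_identifiable and col_ok:
            return Q
    raise EstimationError("could not draw an identifiable synthetic Q-matrix")


def _size_class(k: int, n_misplaced: int) -> str:
    small_max, medium_max = _SIZE_CLASS_CUTOFFS.get(
        k, (int(round(k / 3)), int(round(2 * k / 3)))
    )
    if n_misplaced <= small_max:
        return "small"
    if n_misplaced <= medium_max:
        return "medium"
    return "large"


def _random_derangement(size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform fixed-point-free permutation of ``range(size)`` (rejection)."""
    idx = np.arange(size)
    while True:
        perm = rng.permutation(size)
        if not np.any(perm == idx):
            return perm


def sample_row_permutations(
    Q: WeightMatrix, n: int, rng: np.random.Generator
) -> list[PerturbedQ]:
    """Sample ``n`` row permutations of ``Q`` with graded displacement.

    A uniform random permutation of ``k`` rows displaces almost all of them
    (the expected number of fixed points is 1), which would leave the small
    and medium perturbation classes empty.  To cover the whole perturbation
    range, each draw first picks a displacement count ``m`` uniformly from
    {2, ..., k}, then applies a uniform derangement to a uniformly chosen
    subset of ``m`` rows — i.e. the permutation is uniform among those
    displacing exactly ``m`` rows.  The identity is excluded by construction
    (``m >= 2``; a permutation cannot displace exactly one row).

    ``n_misplaced`` counts positions whose incoming row index differs from
    the original; duplicate row *content* is ignored, so swapping two
    identical rows still counts as two displacements.
    """
    if not isinstance(Q, WeightMatrix):
        Q = WeightMatrix(weights=np.asarray(Q))
    k = Q.n_items
    if k < 2:
        raise ValidationError("need at least two rows to permute")
    if n < 1:
        raise ValidationError("n must be at least 1")
    identity = np.arange(k)
    out: list[PerturbedQ] = []
    for _ in range(n):
        m = int(rng.integers(2, k + 1))
        rows = rng.choice(k, size=m, replace=False)
        perm = identity.copy()
        perm[np.sort(rows)] = np.sort(rows)[_random_derangement(m, rng)]
        misplaced = int(np.sum(perm != identity))
        out.append(
            PerturbedQ(
                Q_perturbed=Q.permuted_rows(perm),
                permutation=perm,
                n_misplaced=misplaced,
                size_class=_size_class(k, misplaced),
            )
        )
    return out


def simulate_rasch_data(
    beta,
    n_persons: int,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Simulate binary responses from the Rasch model.

    Abilities are drawn from Normal(``theta_mean``, ``theta_sd``); each
    response is Bernoulli with logistic probability ``expit(theta - beta)``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.size < 2 or not np.all(np.isfinite(beta)):
        raise ValidationError("beta must be a finite vector of length >= 2")
    if n_persons < 1:
        raise ValidationError("n_persons must be at least 1")
    if theta_sd <= 0:
        raise ValidationError("theta_sd must be positive")
    rng = np.random.default_rng() if rng is None else rng
    theta = rng.normal(theta_mean, theta_sd, size=n_persons)
    logits = theta[:, None] - beta[None, :]
    prob = 1.0 / (1.0 + np.exp(-logits))
    X = (rng.random((n_persons, beta.size)) < prob).astype(np.int8)
    return ResponseMatrix(data=X)


def simulate_lltm_data(
    Q: WeightMatrix,
    eta,
    n_persons: int,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Simulate responses from the LLTM: Rasch data at ``beta = Q eta + c``."""
    if not isinstance(Q, WeightMatrix):
        Q = WeightMatrix(weights=np.asarray(Q))
    if not Q.is_identifiable:
        raise ValidationError("weight matrix is not identifiable")
    beta = reconstruct_item_parameters(np.asarray(eta, dtype=float), Q)
    return simulate_rasch_data(beta, n_persons, theta_mean, theta_sd, rng)


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------


def _lltm_replicate(
    responses: ResponseMatrix,
    rm,
    Q: WeightMatrix,
    config: ScenarioConfig,
    index: int,
    n_misplaced: int | None = None,
    size_class: str | None = None,
) -> ReplicateRecord:
    """Fit one LLTM replicate against a fixed Rasch fit; never raises."""
    extras = {"n_misplaced": n_misplaced, "size_class": size_class}
    if not Q.is_identifiable:
        return ReplicateRecord(replicate=index, converged=False, **extras)
    try:
        lltm = fit_lltm(responses, Q, tol=config.tol, max_iter=config.max_iter)
        if not lltm.converged:
            return ReplicateRecord(replicate=index, converged=False, **extras)
        comp: ComparisonResult = lr_test(rm, lltm)
        r = item_parameter_correlation(
            rm.beta, lltm.beta_reconstructed, method=config.correlation
        )
    except (EstimationError, ValidationError):
        return ReplicateRecord(replicate=index, converged=False, **extras)
    return ReplicateRecord(
        replicate=index,
        converged=True,
        r=r,
        lr_statistic=comp.lr_statistic,
        lr_df=comp.df,
        lr_p=comp.p_value,
        aic_rm=comp.aic_rm,
        bic_rm=comp.bic_rm,
        aic_lltm=comp.aic_lltm,
        bic_lltm=comp.bic_lltm,
        **extras,
    )


def run_scenario1(
    responses: ResponseMatrix, k: int, p: int, config: ScenarioConfig
) -> NullCorrelationDistribution:
    """Random-Q lower benchmark on a fixed dataset.

    Fits the Rasch model once, then for each replicate draws a random
    ``k x p`` weight matrix and fits the LLTM on the same data, recording the
    item-parameter correlation, LR test and information criteria.
    Non-identifiable or non-convergent draws are excluded from summaries and
    counted.

    Raises
    ------
    EstimationError
        If the one-off Rasch fit itself fails.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(data=np.asarray(responses))
    if responses.n_items != k:
        raise ValidationError(f"responses have {responses.n_items} items, expected {k}")
    if config.prop_ones is None:
        raise ValidationError("scenario 1 requires a concrete prop_ones")
    rm = fit_rasch(responses, tol=config.tol, max_iter=config.max_iter)
    if not rm.converged:
        raise EstimationError("Rasch fit on the observed data did not converge")
    rng = np.random.default_rng(config.seed)
    records = []
    for j in range(config.reps):
        Q = simulate_random_q(k, p, config.prop_ones, rng, config.exact_quota)
        records.append(_lltm_replicate(responses, rm, Q, config, j))
    return NullCorrelationDistribution(scenario=1, config=config, records=records)


def run_scenario2(
    responses: ResponseMatrix, Q: WeightMatrix, config: ScenarioConfig
) -> dict[str, NullCorrelationDistribution]:
    """Row-perturbation benchmark around a theoretical Q-matrix.

    Samples ``config.reps`` uniform row permutations of ``Q`` (identity
    excluded), fits the LLTM with each permuted matrix on the observed data,
    and returns one :class:`NullCorrelationDistribution` per displacement
    size class (only classes that occurred), plus a pooled ``"all"`` entry.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(data=np.asarray(responses))
    if not isinstance(Q, WeightMatrix):
        Q = WeightMatrix(weights=np.asarray(Q))
    if Q.n_items != responses.n_items:
        raise ValidationError("weight matrix rows must match the item count")
    rm = fit_rasch(responses, tol=config.tol, max_iter=config.max_iter)
    if not rm.converged:
        raise EstimationError("Rasch fit on the observed data did not converge")
    rng = np.random.default_rng(config.seed)
    perturbed = sample_row_permutations(Q, config.reps, rng)
    records = [
        _lltm_replicate(
            responses,
            rm,
            pq.Q_perturbed,
            config,
            j,
            n_misplaced=pq.n_misplaced,
            size_class=pq.size_class,
        )
        for j, pq in enumerate(perturbed)
    ]
    out: dict[str, NullCorrelationDistribution] = {
        "all": NullCorrelationDistribution(scenario=2, config=config, records=records)
    }
    for cls_name in ("small", "medium", "large"):
        subset = [rec for rec in records if rec.size_class == cls_name]
        if subset:
            out[cls_name] = NullCorrelationDistribution(
                scenario=2, config=config, records=subset
            )
    return out


def run_scenario3(
    Q: WeightMatrix, eta, config: ScenarioConfig
) -> NullCorrelationDistribution:
    """Upper benchmark: datasets generated from a correctly specified LLTM.

    For each replicate a fresh dataset of ``config.persons`` persons is
    simulated from the LLTM with weight matrix ``Q`` and basic parameters
    ``eta``; both models are refitted on it and the correlation, the LR
    decision at ``config.alpha`` and the per-replicate AIC/BIC preferences
    are recorded.  Generator or fit failures become non-convergent records.
    """
    if not isinstance(Q, WeightMatrix):
        Q = WeightMatrix(weights=np.asarray(Q))
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValidationError("eta must be finite")
    if not Q.is_identifiable:
        raise ValidationError("weight matrix is not identifiable")
    rng = np.random.default_rng(config.seed)
    records = []
    for j in range(config.reps):
        data = simulate_lltm_data(
            Q, eta, config.persons, config.theta_mean, config.theta_sd, rng
        )
        try:
            rm = fit_rasch(data, tol=config.tol, max_iter=config.max_iter)
            if not rm.converged:
                records.append(ReplicateRecord(replicate=j, converged=False))
                continue
        except EstimationError:
            records.append(ReplicateRecord(replicate=j, converged=False))
            continue
        records.append(_lltm_replicate(data, rm, Q, config, j))
    return NullCorrelationDistribution(scenario=3, config=config, records=records)
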