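"""Compensatory multidimensional IRT response simulation.

Generates dichotomous response matrices under the compensatory
multidimensional two- and three-parameter logistic models (M2PL/M3PL),

    P(x_ij = 1 | a_i, beta_i, c, theta_j)
        = c + (1 - c) * exp(a_i' theta_j + beta_i) / (1 + exp(a_i' theta_j + beta_i)),

where ``a_i`` is the item discrimination vector, ``beta_i`` an easiness
intercept, ``c`` a common lower asymptote (guessing floor) and ``theta_j``
the examinee's ability vector, drawn multivariate normal with an
equicorrelation structure.

Item discrimination vectors are built from a multidimensional discrimination
(MDISC) magnitude and direction angles: ``a_k = MDISC * cos(angle_k)`` on each
loaded factor.  The fixed angle design splits the test into four equal blocks
so that each latent dimension has items measuring it more strongly than the
others (approximate simple structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SimulationCondition",
    "ItemBank",
    "ThetaPopulation",
    "ResponseMatrix",
    "DimensionDesignError",
    "build_angle_design",
    "sample_item_bank",
    "sample_theta",
    "response_prob",
    "generate_responses",
    "simulate_responses",
]

#: 2-dimension design: four equal item blocks with (factor-1, factor-2) angles.
ANGLE_BLOCKS_2D = ((15.0, 75.0), (30.0, 60.0), (60.0, 30.0), (75.0, 15.0))

#: 4-dimension design: each block loads on a (primary, secondary) factor pair
#: with angles (15deg, 75deg); all other loadings are exactly zero.
FACTOR_PAIRS_4D = ((0, 1), (1, 2), (2, 3), (3, 0))
ANGLES_4D = (15.0, 75.0)

N_ANGLE_BLOCKS = 4


class DimensionDesignError(ValueError):
    """Raised when the angle design does not support the requested layout."""


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    Parameters
    ----------
    n_dims : int
        Number of latent dimensions (2 or 4).
    rho : float
        Common inter-dimension correlation (equicorrelation), in ``[0, 1)``.
    n_examinees : int
        Number of simulated examinees per replication.
    guessing : float, default 0.0
        Lower asymptote ``c``; 0 gives the M2PL, 0.25 the study's M3PL.
    n_items : int, default 40
        Test length; must be divisible by the four angle blocks.
    n_reps : int, default 100
        Number of replicated test forms for this condition.
    """

    n_dims: int
    rho: float
    n_examinees: int
    guessing: float = 0.0
    n_items: int = 40
    n_reps: int = 100

    def __post_init__(self) -> None:
        if self.n_dims not in (2, 4):
            raise DimensionDesignError(
                f"n_dims must be 2 or 4, got {self.n_dims}"
            )
        if not (-1.0 / (self.n_dims - 1) < self.rho < 1.0):
            raise ValueError(
                "rho must give a positive-definite equicorrelation matrix: "
                f"need -1/(n_dims-1) < rho < 1, got {self.rho}"
            )
        if not 0.0 <= self.guessing < 1.0:
            raise ValueError(f"guessing must be in [0, 1), got {self.guessing}")
        if self.n_examinees < 1:
            raise ValueError("n_examinees must be positive")
        if self.n_items % N_ANGLE_BLOCKS != 0:
            raise ValueError(
                f"n_items must be divisible by {N_ANGLE_BLOCKS}, got {self.n_items}"
            )
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    @property
    def label(self) -> str:
        c = f"{self.guessing:g}"
        return (
            f"dims={self.n_dims} rho={self.rho:g} "
            f"N={self.n_examinees} c={c}"
        )


@dataclass(frozen=True)
class ThetaPopulation:
    """Multivariate-normal ability population: mean zero, unit variances."""

    n_dims: int
    corr: np.ndarray

    def __post_init__(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        if corr.shape != (self.n_dims, self.n_dims):
            raise ValueError("corr shape inconsistent with n_dims")
        if not np.allclose(corr, corr.T):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("corr must have unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 0:
            raise ValueError("corr must be positive definite")

    @classmethod
    def equicorrelated(cls, n_dims: int, rho: float) -> "ThetaPopulation":
        corr = np.full((n_dims, n_dims), float(rho))
        np.fill_diagonal(corr, 1.0)
        return cls(n_dims=n_dims, corr=corr)


@dataclass(frozen=True)
class ItemBank:
    """Item parameters of a simulated test form.

    ``a`` holds one discrimination vector per item (row), ``beta`` the
    easiness intercepts, ``c`` the common lower asymptote, ``mdisc`` the
    multidimensional discrimination (Euclidean norm of ``a``) and ``angles``
    the direction angles in degrees (NaN on unloaded factors).
    """

    a: np.ndarray
    beta: np.ndarray
    c: float
    mdisc: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.a, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "mdisc", np.asarray(self.mdisc, dtype=float))
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if np.any(a < 0):
            raise ValueError("discriminations must be non-negative")
        norms = np.sqrt((a**2).sum(axis=1))
        if np.max(np.abs(norms - self.mdisc)) > 1e-10:
            raise ValueError("sqrt(sum a_k^2) must equal mdisc per item")

    @property
    def n_items(self) -> int:
        return self.a.shape[0]

    @property
    def n_dims(self) -> int:
        return self.a.shape[1]


@dataclass(frozen=True)
class ResponseMatrix:
    """N x n dichotomous response matrix with row/column identifiers."""

    scores: np.ndarray
    examinee_ids: tuple = ()
    item_ids: tuple = ()

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-d matrix")
        if not np.isin(scores, (0, 1)).all():
            raise ValueError("scores must contain only 0/1 entries")
        scores = scores.astype(np.int8)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        n_exam, n_items = scores.shape
        exam_ids = self.examinee_ids or tuple(f"p{i + 1}" for i in range(n_exam))
        item_ids = self.item_ids or tuple(f"item{j + 1}" for j in range(n_items))
        if len(exam_ids) != n_exam or len(item_ids) != n_items:
            raise ValueError("identifier lengths inconsistent with scores shape")
        object.__setattr__(self, "examinee_ids", tuple(exam_ids))
        object.__setattr__(self, "item_ids", tuple(item_ids))

    @property
    def n_examinees(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.scores, index=list(self.examinee_ids), columns=list(self.item_ids)
        )

    def to_csv(self, path) -> None:
        """Write as CSV: one row per examinee, header row of item ids."""
        self.to_frame().to_csv(path, index=False)


def build_angle_design(n_dims: int, n_items: int) -> np.ndarray:
    """Per-item direction angles (degrees) for the four-block test design.

    Returns an ``(n_items, n_dims)`` array; entries are NaN on factors an
    item does not load on.  For two dimensions the four equal blocks have
    (factor-1, factor-2) angles (15, 75), (30, 60), (60, 30), (75, 15); for
    four dimensions each block loads on a cyclic factor pair (1,2), (2,3),
    (3,4), (4,1) with angles (15, 75).
    """
    if n_dims not in (2, 4):
        raise DimensionDesignError(f"unsupported n_dims {n_dims}: expected 2 or 4")
    if n_items % N_ANGLE_BLOCKS != 0 or n_items <= 0:
        raise ValueError(
            f"n_items must be a positive multiple of {N_ANGLE_BLOCKS}, got {n_items}"
        )
    block = n_items // N_ANGLE_BLOCKS
    angles = np.full((n_items, n_dims), np.nan)
    for b in range(N_ANGLE_BLOCKS):
        rows = slice(b * block, (b + 1) * block)
        if n_dims == 2:
            angles[rows, 0], angles[rows, 1] = ANGLE_BLOCKS_2D[b]
        else:
            primary, secondary = FACTOR_PAIRS_4D[b]
            angles[rows, primary] = ANGLES_4D[0]
            angles[rows, secondary] = ANGLES_4D[1]
    return angles


def _direction_cosines(angles: np.ndarray) -> np.ndarray:
    cosines = np.where(np.isnan(angles), 0.0, np.cos(np.deg2rad(angles)))
    return cosines


def sample_item_bank(
    cond: SimulationCondition, rng: np.random.Generator
) -> ItemBank:
    """Draw one test form's item parameters.

    MDISC values are log-normal with underlying normal mean 0 and standard
    deviation 0.25 (so the median MDISC is 1); discriminations are
    ``MDISC * cos(angle)`` on the loaded factors; intercepts are
    ``MDISC * z`` with ``z`` a standard-normal draw; the lower asymptote is
    the condition's guessing value, identical across items.
    """
    angles = build_angle_design(cond.n_dims, cond.n_items)
    mdisc = rng.lognormal(mean=0.0, sigma=0.25, size=cond.n_items)
    a = mdisc[:, None] * _direction_cosines(angles)
    beta = mdisc * rng.standard_normal(cond.n_items)
    return ItemBank(a=a, beta=beta, c=cond.guessing, mdisc=mdisc, angles=angles)


def sample_theta(
    n: int, pop: ThetaPopulation, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. ability vectors from the population."""
    if n < 1:
        raise ValueError("n must be positive")
    chol = np.linalg.cholesky(pop.corr)
    z = rng.standard_normal((n, pop.n_dims))
    return z @ chol.T


def response_prob(a, theta, beta, c: float = 0.0):
    """Compensatory M2PL/M3PL success probability.

    ``c + (1 - c) * logistic(a' theta + beta)``; accepts a single item
    (vector ``a``, scalar ``beta``) against one or many theta rows, or full
    bank arrays against a theta matrix (returns examinee x item matrix).
    """
    a = np.asarray(a, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if a.ndim == 1:
        logit = theta @ a + beta
    else:
        logit = theta @ a.T + np.asarray(beta, dtype=float)
    return c + (1.0 - c) * expit(logit)


def bank_response_probs(bank: ItemBank, thetas: np.ndarray) -> np.ndarray:
    """Success-probability matrix (examinees x items) for a whole bank."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if thetas.shape[1] != bank.n_dims:
        raise ValueError(
            f"theta has {thetas.shape[1]} columns but bank has {bank.n_dims} dimensions"
        )
    return response_prob(bank.a, thetas, bank.beta, bank.c)


def generate_responses(
    bank: ItemBank, thetas: np.ndarray, rng: np.random.Generator
) -> ResponseMatrix:
    """Bernoulli-sample a dichotomous response matrix from model probabilities."""
    probs = bank_response_probs(bank, thetas)
    scores = (rng.random(probs.shape) < probs).astype(np.int8)
    return ResponseMatrix(scores=scores)


def simulate_responses(
    cond: SimulationCondition, seed
) -> tuple[ResponseMatrix, ItemBank, np.ndarray]:
    """One full generate cycle: item bank, abilities, responses.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; three
    independent substreams are spawned for the bank, the abilities and the
    Bernoulli sampling so stages can be varied independently.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    bank_ss, theta_ss, resp_ss = ss.spawn(3)
    bank = sample_item_bank(cond, np.random.default_rng(bank_ss))
    pop = ThetaPopulation.equicorrelated(cond.n_dims, cond.rho)
    thetas = sample_theta(cond.n_examinees, pop, np.random.default_rng(theta_ss))
    responses = generate_responses(bank, thetas, np.random.default_rng(resp_ss))
    return responses, bank, thetas
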