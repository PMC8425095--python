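"""Breeding-value model for honeybee colonies.

A colony phenotype is modelled under the infinitesimal model as

    P = BV_mat(queen) + mean worker BV_dir + e,

i.e. the maternal genetic effect of the queen, the mean direct genetic
effect of her worker group, and a non-heritable residual.  Direct and
maternal breeding values are a bivariate normal pair with covariance
``Sigma_BV``; transmission follows haplodiploid rules: drones are haploid
gametes of their dam (half her breeding value plus one Mendelian sampling
term), queens receive half their dam's value, the full value of a single
haploid sire drone, and a dam-side Mendelian term.  Mendelian sampling
variance per meiosis is ``(1 - F)/4 * Sigma_BV`` where ``F`` is the dam's
inbreeding coefficient, so inbreeding erodes within-family variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

ENVIRONMENT = "environment"
FOUNDER = "founder"

__all__ = [
    "ENVIRONMENT",
    "FOUNDER",
    "GeneticSetup",
    "BVPair",
    "QueenRecord",
    "DroneRecord",
    "ColonyRecord",
    "sample_base_queens",
    "sample_environment_drones",
    "meiosis_term",
    "drone_bv",
    "queen_bv",
    "worker_group_bv",
    "colony_performance",
    "expected_performance",
]


class BVPair(NamedTuple):
    """A (direct, maternal) breeding-value pair, in trait units."""

    bv_dir: float
    bv_mat: float


@dataclass(frozen=True)
class GeneticSetup:
    """Base-population (co)variance parameters.

    Parameters
    ----------
    var_dir : float
        Variance of direct breeding values (trait^2).
    var_mat : float
        Variance of maternal breeding values (trait^2).
    corr_dir_mat : float
        Direct-maternal genetic correlation, in [-1, 1].
    var_residual : float
        Residual (environmental) variance of colony performance (trait^2).
    """

    var_dir: float
    var_mat: float
    corr_dir_mat: float = 0.0
    var_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.var_dir < 0 or self.var_mat < 0 or self.var_residual < 0:
            raise ValueError("variances must be non-negative")
        if not -1.0 <= self.corr_dir_mat <= 1.0:
            raise ValueError("corr_dir_mat must lie in [-1, 1]")

    @property
    def cov_dir_mat(self) -> float:
        """Implied direct-maternal covariance."""
        return self.corr_dir_mat * np.sqrt(self.var_dir * self.var_mat)

    def covariance(self) -> np.ndarray:
        """The 2x2 genetic covariance matrix Sigma_BV (dir first)."""
        c = self.cov_dir_mat
        return np.array([[self.var_dir, c], [c, self.var_mat]])

    def _chol(self) -> np.ndarray:
        # Explicit 2x2 lower factor; valid for singular setups (zero
        # variances, |r| = 1) where numpy's cholesky would raise.
        sd_d = np.sqrt(self.var_dir)
        sd_m = np.sqrt(self.var_mat)
        r = self.corr_dir_mat
        return np.array([[sd_d, 0.0], [sd_m * r, sd_m * np.sqrt(1.0 - r * r)]])


@dataclass
class QueenRecord:
    """A diploid female with pedigree, breeding values and mating state."""

    id: int
    birth_year: int
    dam_id: int | str
    sire_drone_id: int | str
    bv: BVPair
    inbreeding: float
    line_id: int
    role: str = "virgin"
    mate_drone_ids: list[int] = field(default_factory=list)
    #: breeding values of the mates, shape (nD, 2); kept alongside the ids
    #: so worker groups and daughters can be formed without a registry scan.
    mate_bvs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [0, 1]")


@dataclass
class DroneRecord:
    """A haploid male: genetically a gamete of his dam (a DPQ)."""

    id: int
    dam_id: int | str
    bv: BVPair


@dataclass
class ColonyRecord:
    """A phenotyped colony: performance and its additive components."""

    queen_id: int
    year_performed: int
    worker_bv: BVPair
    residual: float
    performance: float


def _draw_bv(setup: GeneticSetup, n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` draws from N(0, scale * Sigma_BV), as an (n, 2) array."""
    z = rng.standard_normal((n, 2))
    return np.sqrt(scale) * (z @ setup._chol().T)


def meiosis_terms(
    setup: GeneticSetup, dam_inbreeding: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vector of Mendelian sampling terms, one per dam inbreeding value.

    Row i is a draw from N(0, (1 - F_i)/4 * Sigma_BV).
    """
    f = np.asarray(dam_inbreeding, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("dam inbreeding must lie in [0, 1]")
    z = rng.standard_normal((f.size, 2))
    return np.sqrt((1.0 - f) / 4.0)[:, None] * (z @ setup._chol().T)


def sample_base_queens(setup: GeneticSetup, n: int, rng: np.random.Generator) -> list[BVPair]:
    """Breeding values for ``n`` unrelated, non-inbred base-population queens.

    Draws are i.i.d. bivariate normal with mean zero and covariance Sigma_BV.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [BVPair(*row) for row in _draw_bv(setup, n, 1.0, rng)]


def sample_environment_drones(
    setup: GeneticSetup, n: int, rng: np.random.Generator
) -> list[DroneRecord]:
    """Drones from the unselected environment (burn-in matings).

    Haploid males carry a single gamete, so their genetic variance is half
    that of diploid queens: draws come from N(0, Sigma_BV / 2).  Ids are
    local (negative) placeholders; the breeding scheme registers its own.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows = _draw_bv(setup, n, 0.5, rng)
    return [DroneRecord(id=-(i + 1), dam_id=ENVIRONMENT, bv=BVPair(*row)) for i, row in enumerate(rows)]


def meiosis_term(setup: GeneticSetup, dam_inbreeding: float, rng: np.random.Generator) -> BVPair:
    """One Mendelian sampling term phi ~ N(0, (1 - F)/4 * Sigma_BV)."""
    if not 0.0 <= dam_inbreeding <= 1.0:
        raise ValueError("dam inbreeding must lie in [0, 1]")
    return BVPair(*meiosis_terms(setup, np.array([dam_inbreeding]), rng)[0])


def drone_bv(dpq_bv: BVPair, phi: BVPair) -> BVPair:
    """Breeding value of a drone: half his DPQ dam's value plus her meiosis term."""
    return BVPair(0.5 * dpq_bv.bv_dir + phi.bv_dir, 0.5 * dpq_bv.bv_mat + phi.bv_mat)


def queen_bv(bq_bv: BVPair, sire_drone_bv: BVPair, phi: BVPair) -> BVPair:
    """Breeding value of a daughter queen.

    Half the dam's value, plus the full (haploid) value of the sire drone,
    plus a dam-side Mendelian term; drones produce identical gametes by
    mitosis so there is no sire-side sampling term at this step.
    """
    return BVPair(
        0.5 * bq_bv.bv_dir + sire_drone_bv.bv_dir + phi.bv_dir,
        0.5 * bq_bv.bv_mat + sire_drone_bv.bv_mat + phi.bv_mat,
    )


def worker_group_bv(queen_bv_: BVPair, mate_bvs: Sequence[BVPair]) -> BVPair:
    """Mean breeding value of a queen's worker group.

    Half the queen's value plus the mean of her nD mates' values; the mean
    Mendelian term over thousands of workers is taken as zero.
    """
    if len(mate_bvs) == 0:
        raise ValueError("a mated queen must have at least one mate")
    arr = np.asarray(mate_bvs, dtype=float)
    mean = arr.mean(axis=0)
    return BVPair(0.5 * queen_bv_.bv_dir + mean[0], 0.5 * queen_bv_.bv_mat + mean[1])


def colony_performance(
    queen: QueenRecord,
    worker_bv: BVPair,
    setup: GeneticSetup,
    rng: np.random.Generator,
    year: int = 0,
) -> ColonyRecord:
    """Realized colony performance P = queen maternal BV + worker direct BV + e."""
    e = float(rng.normal(0.0, np.sqrt(setup.var_residual)))
    return ColonyRecord(
        queen_id=queen.id,
        year_performed=year,
        worker_bv=worker_bv,
        residual=e,
        performance=queen.bv.bv_mat + worker_bv.bv_dir + e,
    )


def expected_performance(queen_bv_: BVPair, mate_bvs: Sequence[BVPair]) -> float:
    """Expectation of a colony's performance given its queen and her mates.

    E(P) = BV_mat(Q) + BV_dir(Q)/2 + mean direct BV of the mates.
    """
    if len(mate_bvs) == 0:
        raise ValueError("a mated queen must have at least one mate")
    mean_dir = float(np.mean([m.bv_dir for m in mate_bvs]))
    return queen_bv_.bv_mat + 0.5 * queen_bv_.bv_dir + mean_dir
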