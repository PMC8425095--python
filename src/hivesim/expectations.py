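"""Closed-form expectations for colony phenotypic variance and heritability.

With performance P = BV_mat(Q) + mean worker BV_dir + e and a queen mated
to ``nD`` drones of a single sire queen, the initial phenotypic variance is

    sigma_P^2 = var_mat + (nD + 2)/(4 nD) * var_dir + cov_dir_mat + var_e.

The direct effect enters with weight (nD + 2)/(4 nD): 3/4 under monoandry,
falling toward 1/4 as polyandry dilutes the between-drone variance.
Heritabilities are ratios of the genetic variances to sigma_P^2.  These
formulas are not used inside the simulator (which only records empirical
moments); they serve as oracles and as a reporting convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import GeneticSetup

__all__ = [
    "VarianceReport",
    "drone_weight",
    "phenotypic_variance",
    "heritabilities",
    "variance_in_year",
    "variance_table",
]


@dataclass(frozen=True)
class VarianceReport:
    """Phenotypic variance and the two heritabilities it implies."""

    phenotypic_variance: float
    h2_dir: float
    h2_mat: float


def drone_weight(n_drones: int) -> float:
    """Weight (nD + 2) / (4 nD) of the direct variance in sigma_P^2."""
    if n_drones < 1:
        raise ValueError("n_drones must be >= 1")
    return (n_drones + 2) / (4.0 * n_drones)


def phenotypic_variance(setup: GeneticSetup, n_drones: int) -> float:
    """Expected phenotypic variance of initial-population colonies."""
    return (
        setup.var_mat
        + drone_weight(n_drones) * setup.var_dir
        + setup.cov_dir_mat
        + setup.var_residual
    )


def heritabilities(setup: GeneticSetup, n_drones: int) -> VarianceReport:
    """Direct and maternal heritabilities at a given polyandry level."""
    v_p = phenotypic_variance(setup, n_drones)
    if v_p <= 0:
        raise ValueError("phenotypic variance must be positive")
    return VarianceReport(
        phenotypic_variance=v_p,
        h2_dir=setup.var_dir / v_p,
        h2_mat=setup.var_mat / v_p,
    )


def variance_in_year(
    genetic_covariance: np.ndarray, n_drones: int, var_residual: float
) -> float:
    """Approximate phenotypic variance in year t from the year t-1 queen
    (co)variances (direct first), assuming unrelated dams and sire queens.

    Reduces to the initial-population formula when fed the base
    covariance matrix; under selection it is only an approximation, since
    breeding queens and drone-producing queens become related.
    """
    c = np.asarray(genetic_covariance, dtype=float)
    if c.shape != (2, 2) or not np.allclose(c, c.T):
        raise ValueError("genetic covariance must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(c)[0] < -1e-9:
        raise ValueError("genetic covariance must be positive semi-definite")
    return float(c[1, 1] + drone_weight(n_drones) * c[0, 0] + c[0, 1] + var_residual)


def variance_table(
    setups: dict[int | str, GeneticSetup], n_drones_list: list[int]
) -> pd.DataFrame:
    """Grid of sigma_P^2 / h2_dir / h2_mat per setup and polyandry level.

    Values are kept at full precision; round at the display layer.
    """
    rows = []
    for label, setup in setups.items():
        for nd in n_drones_list:
            rep = heritabilities(setup, nd)
            rows.append(
                {
                    "setup": label,
                    "n_drones": nd,
                    "var_dir": setup.var_dir,
                    "var_mat": setup.var_mat,
                    "corr_dir_mat": setup.corr_dir_mat,
                    "sigma2_P": rep.phenotypic_variance,
                    "h2_dir": rep.h2_dir,
                    "h2_mat": rep.h2_mat,
                }
            )
    return pd.DataFrame(rows)
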