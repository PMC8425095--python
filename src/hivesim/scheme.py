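"""Annual cycle of a small closed honeybee breeding program.

Each year, 6 breeding queens produce 24 virgin queens and 36 potential
drone-producing queens (pDPQ) apiece.  A first winter randomly removes
25% of the colonies, leaving 108 candidate queens (and 162 pDPQ) to be
phenotyped the following year.  The 6 next breeding queens are selected
from the 108 candidates either by mass selection (best 6 overall) or
within maternal lines (best per line, lines conserved by splitting when
one goes extinct).  Potential DPQ face a second winter (one third lost,
108 of the initial 216 surviving both), after which sires are chosen in
two steps: the 4 sib families with the best mean colony performance, then
the 3 best survivors within each.  The resulting 12 DPQ produce all
drones two years after their birth; each newly emerged queen is mated to
``nD`` drones of a single randomly chosen DPQ, with the four DPQ families
contributing to equal numbers of queens.  During the first three years
(building up the population) drones instead come from the unselected
environment; the population closes on the sire path in year 4.

Selection acts on raw colony performance only; no pedigree-based
(BLUP-type) evaluation is used.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genetics import (
    ENVIRONMENT,
    FOUNDER,
    BVPair,
    GeneticSetup,
    QueenRecord,
    _draw_bv,
    meiosis_terms,
)
from .kinship import KinshipTable

__all__ = [
    "SchemeConfig",
    "ReplicateFailure",
    "winter_cull",
    "select_breeding_queens",
    "select_dpq",
    "assign_matings",
    "produce_generation",
    "phenotype_colonies",
    "run_replicate",
    "YEARLY_FIELDS",
]


class ReplicateFailure(RuntimeError):
    """The population hit a state the breeding plan cannot recover from."""


@dataclass(frozen=True)
class SchemeConfig:
    """Demography and selection settings of the breeding plan."""

    n_breeding_queens: int = 6
    n_virgin_per_bq: int = 24
    n_pdpq_per_bq: int = 36
    first_winter_survival: float = 0.75
    second_winter_survival: float = 2.0 / 3.0
    n_dpq_families: int = 4
    n_dpq_per_family: int = 3
    n_drones_per_queen: int = 8
    selection_strategy: str = "within_line"  # "mass" | "within_line" | "random"
    burn_in_years: int = 3
    total_years: int = 23
    keep_generations: int = 3
    include_pdpq_in_stats: bool = False

    def __post_init__(self) -> None:
        for name in (
            "n_breeding_queens", "n_virgin_per_bq", "n_pdpq_per_bq",
            "n_dpq_families", "n_dpq_per_family", "n_drones_per_queen",
            "burn_in_years", "total_years", "keep_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("first_winter_survival", "second_winter_survival"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.selection_strategy not in ("mass", "within_line", "random"):
            raise ValueError(f"unknown selection strategy: {self.selection_strategy!r}")

    @property
    def n_candidates(self) -> int:
        """Candidate queen colonies phenotyped each year (e.g. 108 of 144)."""
        return round(self.first_winter_survival * self.n_breeding_queens * self.n_virgin_per_bq)

    @property
    def n_pdpq_after_first_winter(self) -> int:
        return round(self.first_winter_survival * self.n_breeding_queens * self.n_pdpq_per_bq)

    @property
    def n_pdpq_after_second_winter(self) -> int:
        return round(self.second_winter_survival * self.n_pdpq_after_first_winter)


def winter_cull(items: Sequence, survivor_count: int, rng: np.random.Generator) -> list:
    """Keep exactly ``survivor_count`` random items (fixed-count mortality).

    The surviving count is deterministic, the identities random, matching
    the fixed post-winter colony numbers of the plan.
    """
    n = len(items)
    if survivor_count > n:
        raise ValueError(f"cannot keep {survivor_count} of {n} colonies")
    if survivor_count == n:
        return list(items)
    keep = np.sort(rng.choice(n, size=survivor_count, replace=False))
    return [items[i] for i in keep]


def _ranked_indices(performances: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices sorted by performance, best first, ties broken at random."""
    shuffle = rng.permutation(len(performances))
    order = shuffle[np.argsort(-performances[shuffle], kind="stable")]
    return order


def select_breeding_queens(
    colonies: Sequence[tuple[QueenRecord, float]],
    strategy: str,
    rng: np.random.Generator,
    n_select: int = 6,
    lines: Sequence[int] | None = None,
) -> list[QueenRecord]:
    """Choose the next breeding queens from the phenotyped candidates.

    ``mass`` takes the best ``n_select`` overall; ``within_line`` takes
    the best candidate of each maternal line, splitting a randomly chosen
    surviving line in two (its two best candidates both selected, the
    second relabelled) whenever a line has no surviving candidate, so the
    number of lines is conserved; ``random`` disables selection.
    """
    if len(colonies) < n_select:
        raise ReplicateFailure(
            f"only {len(colonies)} candidate colonies for {n_select} breeding queens"
        )
    perfs = np.array([p for _, p in colonies])

    if strategy == "random":
        chosen = rng.choice(len(colonies), size=n_select, replace=False)
        return [colonies[i][0] for i in chosen]

    if strategy == "mass":
        order = _ranked_indices(perfs, rng)
        return [colonies[i][0] for i in order[:n_select]]

    if strategy != "within_line":
        raise ValueError(f"unknown selection strategy: {strategy!r}")
    if lines is None:
        lines = sorted({q.line_id for q, _ in colonies})
    if len(lines) != n_select:
        raise ValueError("within-line selection needs one line slot per breeding queen")

    by_line: dict[int, list[int]] = defaultdict(list)
    order = _ranked_indices(perfs, rng)
    for i in order:
        by_line[colonies[i][0].line_id].append(i)  # best-first within line

    selected: list[QueenRecord] = []
    taken: dict[int, int] = {}  # line -> how many already taken
    for line in lines:
        if by_line.get(line):
            selected.append(colonies[by_line[line][0]][0])
            taken[line] = 1
    missing = [line for line in lines if line not in taken]
    for line in missing:
        donors = [l for l in by_line if len(by_line[l]) > taken.get(l, 0)]
        if not donors:
            raise ReplicateFailure("no surviving line left to split")
        donor = donors[rng.integers(len(donors))]
        idx = by_line[donor][taken.get(donor, 0)]
        queen = colonies[idx][0]
        queen.line_id = line  # the split founds a new line under the freed label
        taken[donor] = taken.get(donor, 0) + 1
        selected.append(queen)
    if len(selected) < n_select:
        raise ReplicateFailure("fewer surviving candidates than breeding queens required")
    return selected


def select_dpq(
    evaluated: dict[int, list[tuple[QueenRecord, float]]],
    surviving: dict[int, list[tuple[QueenRecord, float]]],
    rng: np.random.Generator,
    n_families: int = 4,
    n_per_family: int = 3,
    strategy: str = "mass",
) -> dict[int, list[QueenRecord]]:
    """Two-step sire selection among potential DPQ sib families.

    Step 1 ranks families by the mean colony performance of their members
    phenotyped after the first winter and picks the ``n_families`` best
    that still have at least one second-winter survivor (a fully extinct
    family is replaced by the next best ranking family with a survivor).
    Step 2 keeps the up-to-``n_per_family`` best survivors per family; a
    family with only one or two survivors still supplies its full share
    of drones.  ``strategy="random"`` disables both ranking steps.
    """
    labels = list(evaluated)
    with_survivors = [f for f in labels if surviving.get(f)]
    if len(with_survivors) < n_families:
        raise ReplicateFailure(
            f"only {len(with_survivors)} DPQ families with survivors, need {n_families}"
        )
    if strategy == "random":
        chosen = [with_survivors[i] for i in rng.choice(len(with_survivors), n_families, replace=False)]
        out: dict[int, list[QueenRecord]] = {}
        for f in chosen:
            group = surviving[f]
            k = min(n_per_family, len(group))
            picks = rng.choice(len(group), size=k, replace=False)
            out[f] = [group[i][0] for i in picks]
        return out

    means = np.array(
        [np.mean([p for _, p in evaluated[f]]) if evaluated[f] else -np.inf for f in labels]
    )
    rank = _ranked_indices(means, rng)
    chosen = [labels[i] for i in rank if surviving.get(labels[i])][:n_families]
    out = {}
    for f in chosen:
        group = surviving[f]
        perfs = np.array([p for _, p in group])
        order = _ranked_indices(perfs, rng)
        out[f] = [group[i][0] for i in order[: min(n_per_family, len(group))]]
    return out


def assign_matings(
    queens: Sequence[QueenRecord],
    dpq_by_family: dict[int, list[QueenRecord]] | None,
    n_drones: int,
    rng: np.random.Generator,
    kinship: KinshipTable,
    setup: GeneticSetup,
    year: int,
) -> dict[int, int | str]:
    """Mate every queen to ``n_drones`` drones of a single source.

    In burn-in years (``dpq_by_family is None``) drones come from the
    unselected environment: unrelated, breeding values drawn from
    N(0, Sigma_BV / 2).  Otherwise each queen is assigned one DPQ — the
    families contribute to equal numbers of queens (balanced assignment,
    remainder at random), the DPQ drawn uniformly within the family — and
    her drones are bred from it with the DPQ's own Mendelian variance.
    Returns a map queen id -> sire source (DPQ id or "environment").
    """
    n = len(queens)
    sources: dict[int, int | str] = {}
    if n == 0:
        return sources
    if dpq_by_family is None:
        bvs = _draw_bv(setup, n * n_drones, 0.5, rng)
        for i, q in enumerate(queens):
            ids = [kinship.add_drone(ENVIRONMENT, year) for _ in range(n_drones)]
            q.mate_drone_ids = ids
            q.mate_bvs = bvs[i * n_drones : (i + 1) * n_drones]
            sources[q.id] = ENVIRONMENT
        return sources

    if not dpq_by_family or not any(dpq_by_family.values()):
        raise ReplicateFailure("no drone-producing queens available in a closed year")
    labels = list(dpq_by_family)
    reps, rem = divmod(n, len(labels))
    fam_assign = labels * reps + [labels[i] for i in rng.choice(len(labels), rem, replace=False)]
    fam_assign = [fam_assign[i] for i in rng.permutation(n)]

    dpq_choice: list[QueenRecord] = []
    for f in fam_assign:
        group = dpq_by_family[f]
        dpq_choice.append(group[rng.integers(len(group))])

    dpq_f = np.repeat([d.inbreeding for d in dpq_choice], n_drones)
    phi = meiosis_terms(setup, dpq_f, rng)
    dpq_bv = np.repeat([[d.bv.bv_dir, d.bv.bv_mat] for d in dpq_choice], n_drones, axis=0)
    drone_bvs = 0.5 * dpq_bv + phi
    for i, q in enumerate(queens):
        d = dpq_choice[i]
        q.mate_drone_ids = [kinship.add_drone(d.id, year) for _ in range(n_drones)]
        q.mate_bvs = drone_bvs[i * n_drones : (i + 1) * n_drones]
        sources[q.id] = d.id
    return sources


def produce_generation(
    breeding_queens: Sequence[QueenRecord],
    config: SchemeConfig,
    kinship: KinshipTable,
    setup: GeneticSetup,
    rng: np.random.Generator,
    year: int,
) -> tuple[list[QueenRecord], list[QueenRecord]]:
    """Breed this year's cohort: virgin queens and potential DPQ.

    Each daughter's sire drone is drawn uniformly among her dam's mates
    (independently per daughter); her breeding value is half the dam's
    plus the sire drone's plus a dam-side Mendelian term scaled by the
    dam's inbreeding, and her own F is the coancestry of dam and sire.
    """
    per_bq = config.n_virgin_per_bq + config.n_pdpq_per_bq
    dams: list[QueenRecord] = []
    for bq in breeding_queens:
        if not bq.mate_drone_ids:
            raise ValueError(f"breeding queen {bq.id} is not mated")
        dams.extend([bq] * per_bq)
    total = len(dams)

    n_mates = np.array([len(d.mate_drone_ids) for d in dams])
    sire_pick = rng.integers(0, n_mates)
    dam_bv = np.array([[d.bv.bv_dir, d.bv.bv_mat] for d in dams])
    sire_bv = np.array([d.mate_bvs[k] for d, k in zip(dams, sire_pick)])
    phi = meiosis_terms(setup, np.array([d.inbreeding for d in dams]), rng)
    bv = 0.5 * dam_bv + sire_bv + phi

    dam_ids = [d.id for d in dams]
    sire_ids = [d.mate_drone_ids[k] for d, k in zip(dams, sire_pick)]
    ids, F = kinship.add_females(dam_ids, sire_ids, birth_year=year)

    virgins: list[QueenRecord] = []
    pdpqs: list[QueenRecord] = []
    for j in range(total):
        within = j % per_bq
        role = "virgin" if within < config.n_virgin_per_bq else "potential_dpq"
        q = QueenRecord(
            id=int(ids[j]),
            birth_year=year,
            dam_id=dam_ids[j],
            sire_drone_id=sire_ids[j],
            bv=BVPair(*bv[j]),
            inbreeding=float(F[j]),
            line_id=dams[j].line_id,
            role=role,
        )
        (virgins if role == "virgin" else pdpqs).append(q)
    return virgins, pdpqs


def phenotype_colonies(
    queens: Sequence[QueenRecord],
    setup: GeneticSetup,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realized performances of the colonies headed by ``queens``.

    P = queen maternal BV + (queen direct BV / 2 + mean mate direct BV)
    + residual; the parenthesis is the worker-group mean direct value.
    """
    n = len(queens)
    bd = np.array([q.bv.bv_dir for q in queens])
    bm = np.array([q.bv.bv_mat for q in queens])
    mate_dir = np.array([q.mate_bvs[:, 0].mean() for q in queens])
    e = rng.normal(0.0, np.sqrt(setup.var_residual), size=n)
    return bm + 0.5 * bd + mate_dir + e


YEARLY_FIELDS = (
    "mean_F",
    "mean_P",
    "var_P",
    "mean_bv_dir",
    "var_bv_dir",
    "mean_bv_mat",
    "var_bv_mat",
    "corr_dir_mat",
)


def _cohort_stats(queens: Sequence[QueenRecord], perfs: np.ndarray) -> dict[str, float]:
    bd = np.array([q.bv.bv_dir for q in queens])
    bm = np.array([q.bv.bv_mat for q in queens])
    if bd.std() > 0 and bm.std() > 0:
        corr = float(np.corrcoef(bd, bm)[0, 1])
    else:
        corr = 0.0
    return {
        "mean_F": float(np.mean([q.inbreeding for q in queens])),
        "mean_P": float(perfs.mean()),
        "var_P": float(perfs.var(ddof=1)),
        "mean_bv_dir": float(bd.mean()),
        "var_bv_dir": float(bd.var(ddof=1)),
        "mean_bv_mat": float(bm.mean()),
        "var_bv_mat": float(bm.var(ddof=1)),
        "corr_dir_mat": corr,
    }


def run_replicate(
    setup: GeneticSetup,
    config: SchemeConfig,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate one replicate of the full breeding plan.

    Returns per-year series (index 0 = year 1): statistics of the queens
    born that year that survived the first winter (the phenotyped
    candidates) and of their colony performances, realized the following
    year — so index 22 holds queens born in year 23 with performances
    from year 24.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kin = KinshipTable(capacity=2048)
    lines = list(range(config.n_breeding_queens))

    founder_bv = _draw_bv(setup, config.n_breeding_queens, 1.0, rng)
    bqs: list[QueenRecord] = []
    for i in range(config.n_breeding_queens):
        fid = kin.add_founder_female(birth_year=0)
        bqs.append(
            QueenRecord(
                id=fid, birth_year=0, dam_id=FOUNDER, sire_drone_id=FOUNDER,
                bv=BVPair(*founder_bv[i]), inbreeding=0.0, line_id=lines[i],
                role="breeding",
            )
        )
    assign_matings(bqs, None, config.n_drones_per_queen, rng, kin, setup, year=0)

    out: dict[str, np.ndarray] = {k: np.full(config.total_years, np.nan) for k in YEARLY_FIELDS}
    out["year"] = np.arange(1, config.total_years + 1, dtype=float)

    # pDPQ of the previous cohort, phenotyped, awaiting their second winter
    pdpq_prev: dict[int, list[tuple[QueenRecord, float]]] | None = None
    dpq_active: dict[int, list[QueenRecord]] | None = None

    for t in range(1, config.total_years + 1):
        virgins, pdpqs = produce_generation(bqs, config, kin, setup, rng, year=t)

        if t <= config.burn_in_years:
            source = None
        else:
            if not dpq_active:
                raise ReplicateFailure(f"no DPQ cohort available in closed year {t}")
            source = dpq_active
        assign_matings(virgins + pdpqs, source, config.n_drones_per_queen, rng, kin, setup, year=t)

        candidates = winter_cull(virgins, config.n_candidates, rng)
        pdpq_surv = winter_cull(pdpqs, config.n_pdpq_after_first_winter, rng)

        # phenotyping happens in calendar year t + 1
        cand_perf = phenotype_colonies(candidates, setup, rng)
        pdpq_perf = phenotype_colonies(pdpq_surv, setup, rng)

        if config.include_pdpq_in_stats:
            stat_queens = list(candidates) + list(pdpq_surv)
            stat_perf = np.concatenate([cand_perf, pdpq_perf])
        else:
            stat_queens, stat_perf = candidates, cand_perf
        for k, v in _cohort_stats(stat_queens, stat_perf).items():
            out[k][t - 1] = v

        bqs = select_breeding_queens(
            list(zip(candidates, cand_perf)), config.selection_strategy, rng,
            n_select=config.n_breeding_queens, lines=lines,
        )
        for q in bqs:
            q.role = "breeding"

        # second winter and sire selection for the pDPQ born last year
        dpq_active = None
        if pdpq_prev is not None:
            flat = [qp for group in pdpq_prev.values() for qp in group]
            survivors = winter_cull(flat, config.n_pdpq_after_second_winter, rng)
            if t + 1 > config.burn_in_years:  # their drones will actually be used
                surviving: dict[int, list[tuple[QueenRecord, float]]] = defaultdict(list)
                for q, p in survivors:
                    surviving[q.dam_id].append((q, p))
                dpq_active = select_dpq(
                    pdpq_prev, surviving, rng,
                    n_families=config.n_dpq_families,
                    n_per_family=config.n_dpq_per_family,
                    strategy="random" if config.selection_strategy == "random" else "mass",
                )
                for group in dpq_active.values():
                    for q in group:
                        q.role = "dpq"

        grouped: dict[int, list[tuple[QueenRecord, float]]] = defaultdict(list)
        for q, p in zip(pdpq_surv, pdpq_perf):
            grouped[q.dam_id].append((q, p))
        pdpq_prev = grouped

        kin.prune(t, config.keep_generations)

    return out
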