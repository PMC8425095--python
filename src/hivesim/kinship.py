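"""Coancestry and inbreeding under haplodiploid transmission.

Haplodiploid inheritance follows the same rules as X-linked genes (no
male recombination): a female carries two alleles, one sampled from her
dam and the single allele of her haploid sire; a drone carries one allele
sampled from his dam.  Coancestry f(i, j) is the probability that one
allele drawn at random from each of i and j is identical by descent.  The
tabular recursions (parents before offspring) are:

* founder female:            f(i, i) = 1/2, f to everyone prior 0
* drone d of dam m:          f(d, j) = f(m, j) for prior j, f(d, d) = 1
* female i of dam m, sire s: f(i, j) = (f(m, j) + f(s, j)) / 2 for prior j,
                             F_i = f(m, s), f(i, i) = (1 + F_i) / 2

A female's inbreeding coefficient equals the coancestry of her parents,
and the numerator relationship between two females is 2 f.

Implementation note: the dense symmetric table stores rows for females
and for those drones that have sired offspring.  A drone without
descendants is held as a lightweight record, because until he has
descendants his coancestry with anyone else equals his dam's (his allele
is one random dam allele); he is promoted to a full row — with the exact
tabular rule above — the first time he appears as a sire.  Most drones
are mates of queens that are never selected, so this keeps the table
small and lets a whole year's cohort of daughters be inserted with a few
vectorized array operations, with results identical to running the
tabular method over every individual.

``gene_drop_kinship`` provides an independent Monte Carlo oracle: alleles
are dropped through the pedigree and IBD probabilities estimated by
simulation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .genetics import ENVIRONMENT, FOUNDER

__all__ = ["KinshipTable", "PedigreeError", "gene_drop_kinship"]


class PedigreeError(KeyError):
    """An operation referenced an individual the table does not know."""


class KinshipTable:
    """Incremental haplodiploid coancestry table with generation pruning."""

    def __init__(self, capacity: int = 256):
        # entries beyond the first _n rows/cols are never read, so the
        # backing buffer is left uninitialized
        self._f = np.empty((capacity, capacity))
        self._n = 0
        self._next_id = 0
        self._row: dict[int, int] = {}  # materialized id -> row
        self._ids: list[int] = []
        self._ploidy: list[str] = []  # "F" female, "D" drone, per row
        self._birth: list[int] = []
        self._inbreeding: list[float] = []  # females; 0.0 placeholder for drones
        self._dam: list[int | str] = []
        self._sire: list[int | str] = []  # FOUNDER for drones
        # drones without descendants: id -> (dam id or ENVIRONMENT, birth year)
        self._virtual: dict[int, tuple[int | str, int]] = {}

    # -- bookkeeping ---------------------------------------------------

    def __len__(self) -> int:
        return self._n + len(self._virtual)

    @property
    def n_rows(self) -> int:
        return self._n

    @property
    def ids(self) -> list[int]:
        return list(self._ids) + list(self._virtual)

    def __contains__(self, ident: int) -> bool:
        return ident in self._row or ident in self._virtual

    def is_drone(self, ident: int) -> bool:
        if ident in self._virtual:
            return True
        if ident in self._row:
            return self._ploidy[self._row[ident]] == "D"
        raise PedigreeError(f"unknown individual: {ident!r}")

    def _grow(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._f.shape[0]:
            return
        cap = max(need, 2 * self._f.shape[0])
        f = np.empty((cap, cap))
        f[: self._n, : self._n] = self._f[: self._n, : self._n]
        self._f = f

    def _female_row(self, ident: int | str, what: str = "individual") -> int:
        row = self._row.get(ident) if not isinstance(ident, str) else None
        if row is None or self._ploidy[row] != "F":
            raise PedigreeError(f"unknown or non-female {what}: {ident!r}")
        return row

    def _append_row(
        self,
        ident: int,
        ploidy: str,
        birth_year: int,
        inbreeding: float,
        dam: int | str,
        sire: int | str,
    ) -> int:
        i = self._n
        self._n += 1
        self._row[ident] = i
        self._ids.append(ident)
        self._ploidy.append(ploidy)
        self._birth.append(birth_year)
        self._inbreeding.append(inbreeding)
        self._dam.append(dam)
        self._sire.append(sire)
        return i

    # -- insertion -----------------------------------------------------

    def add_founder_female(self, birth_year: int = 0) -> int:
        """Register an unrelated, non-inbred base-population female."""
        self._grow(1)
        ident = self._next_id
        self._next_id += 1
        i = self._append_row(ident, "F", birth_year, 0.0, FOUNDER, FOUNDER)
        self._f[i, : i + 1] = 0.0
        self._f[: i + 1, i] = 0.0
        self._f[i, i] = 0.5
        return ident

    def add_drone(self, dam_id: int | str, birth_year: int = 0) -> int:
        """Register a drone of a tracked dam, or an environment drone.

        Environment drones are founders with a single allele: coancestry 0
        to everyone, 1 to themselves.
        """
        if dam_id != ENVIRONMENT:
            self._female_row(dam_id, "dam")
        ident = self._next_id
        self._next_id += 1
        self._virtual[ident] = (dam_id, birth_year)
        return ident

    def _materialize_drones(self, drone_ids: Iterable[int]) -> None:
        """Give full tabular rows to drones about to become sires."""
        todo = [d for d in dict.fromkeys(drone_ids) if d in self._virtual]
        if not todo:
            return
        self._grow(len(todo))
        for d in todo:
            dam, by = self._virtual.pop(d)
            i = self._append_row(d, "D", by, 0.0, dam, FOUNDER)
            if dam == ENVIRONMENT:
                self._f[i, :i] = 0.0
                self._f[:i, i] = 0.0
            else:
                r = self._female_row(dam, "dam")
                self._f[i, : i] = self._f[r, : i]
                self._f[: i, i] = self._f[: i, r]
            self._f[i, i] = 1.0

    def add_female(self, dam_id: int | str, sire_drone_id: int, birth_year: int = 0) -> int:
        """Register a daughter of a tracked dam and a tracked sire drone."""
        ids, _ = self.add_females([dam_id], [sire_drone_id], birth_year)
        return int(ids[0])

    def add_females(
        self,
        dam_ids: Sequence[int],
        sire_drone_ids: Sequence[int],
        birth_year: int = 0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized insertion of a cohort of daughters.

        All parents must already be present and no daughter may be an
        ancestor of another (which holds within one year's cohort).
        Returns the new ids and their inbreeding coefficients.
        """
        m = len(dam_ids)
        if m == 0:
            return np.empty(0, dtype=int), np.empty(0)
        for s in sire_drone_ids:
            if s not in self._virtual and (
                s not in self._row or self._ploidy[self._row[s]] != "D"
            ):
                raise PedigreeError(f"unknown sire drone: {s!r}")
        self._materialize_drones(sire_drone_ids)
        a = np.array([self._female_row(d, "dam") for d in dam_ids])
        s = np.array([self._row[x] for x in sire_drone_ids])

        n = self._n
        M = self._f[:n, :n]
        new_old = 0.5 * (M[a, :] + M[s, :])
        # guard against accumulated floating-point drift just outside [0, 1]
        F_new = np.clip(M[a, s], 0.0, 1.0)
        new_new = 0.25 * (M[np.ix_(a, a)] + M[np.ix_(a, s)] + M[np.ix_(s, a)] + M[np.ix_(s, s)])
        np.fill_diagonal(new_new, 0.5 * (1.0 + F_new))

        self._grow(m)
        self._f[n : n + m, :n] = new_old
        self._f[:n, n : n + m] = new_old.T
        self._f[n : n + m, n : n + m] = new_new

        ids = np.arange(self._next_id, self._next_id + m)
        self._next_id += m
        for k in range(m):
            self._append_row(
                int(ids[k]), "F", birth_year, float(F_new[k]), dam_ids[k], sire_drone_ids[k]
            )
        return ids, F_new

    # -- queries -------------------------------------------------------

    def inbreeding(self, ident: int) -> float:
        """Inbreeding coefficient F of a tracked female."""
        return self._inbreeding[self._female_row(ident)]

    def birth_year(self, ident: int) -> int:
        if ident in self._virtual:
            return self._virtual[ident][1]
        if ident in self._row:
            return self._birth[self._row[ident]]
        raise PedigreeError(f"unknown individual: {ident!r}")

    def coancestry(self, i: int, j: int) -> float:
        """Coancestry f(i, j); handles females, drones and mixtures."""
        if i not in self or j not in self:
            raise PedigreeError(f"unknown individual in pair ({i!r}, {j!r})")
        if i == j:
            if i in self._virtual:
                return 1.0
            r = self._row[i]
            return 1.0 if self._ploidy[r] == "D" else float(self._f[r, r])
        # a drone without descendants shares his dam's coancestries
        for _ in range(2):
            if i in self._virtual:
                dam, _y = self._virtual[i]
                if dam == ENVIRONMENT:
                    return 0.0
                i = dam
            if j in self._virtual:
                dam, _y = self._virtual[j]
                if dam == ENVIRONMENT:
                    return 0.0
                j = dam
            if i == j:  # two virtual drones of the same dam
                r = self._row[i]
                return float(self._f[r, r])
        return float(self._f[self._row[i], self._row[j]])

    def relationship(self, i: int, j: int) -> float:
        """Numerator relationship between two females: 2 f(i, j)."""
        return 2.0 * self.coancestry(i, j)

    def inbreeding_of_cross(self, dam_id: int, drone_id: int) -> float:
        """F of a daughter of this dam x drone pair: f(dam, drone)."""
        self._female_row(dam_id, "dam")
        if drone_id not in self or not self.is_drone(drone_id):
            raise PedigreeError(f"unknown drone: {drone_id!r}")
        return self.coancestry(dam_id, drone_id)

    # -- pruning -------------------------------------------------------

    def prune(self, current_year: int, keep_generations: int = 3) -> "KinshipTable":
        """Drop individuals older than ``keep_generations`` years that are
        not parents of any retained individual.

        Retained coancestries and inbreeding coefficients are copied
        verbatim, so pruning never alters any retained value.
        """
        if keep_generations < 1:
            raise ValueError("keep_generations must be >= 1")
        cutoff = current_year - keep_generations

        keep = {i for i, by in zip(self._ids, self._birth) if by >= cutoff}
        # parents of retained individuals stay, so any future daughter of a
        # retained female computes the same F as in the unpruned table
        for ident in list(keep):
            r = self._row[ident]
            for parent in (self._dam[r], self._sire[r]):
                if parent in self._row:
                    keep.add(parent)
        kept_virtual = {
            d for d, (dam, by) in self._virtual.items() if by >= cutoff
        }
        for d in kept_virtual:
            dam = self._virtual[d][0]
            if dam in self._row:
                keep.add(dam)

        rows = sorted(self._row[i] for i in keep)
        sub = self._f[np.ix_(rows, rows)].copy()
        cap = max(256, len(rows) + 1024)
        f = np.empty((cap, cap))
        f[: len(rows), : len(rows)] = sub

        old_ids, old_pl, old_by = self._ids, self._ploidy, self._birth
        old_F, old_dam, old_sire = self._inbreeding, self._dam, self._sire
        self._f = f
        self._n = 0
        self._row = {}
        self._ids, self._ploidy, self._birth = [], [], []
        self._inbreeding, self._dam, self._sire = [], [], []
        for r in rows:
            self._append_row(old_ids[r], old_pl[r], old_by[r], old_F[r], old_dam[r], old_sire[r])
        self._virtual = {d: self._virtual[d] for d in kept_virtual}
        return self

    # -- export --------------------------------------------------------

    def export_pedigree(self) -> list[tuple[int, str, int | str, int | str]]:
        """Pedigree as (id, ploidy, dam, sire) rows in topological order.

        Ploidy is ``"F"`` (diploid female) or ``"D"`` (haploid drone);
        founder parents are the sentinels ``"founder"``/``"environment"``.
        """
        rows: list[tuple[int, str, int | str, int | str]] = []
        for k, ident in enumerate(self._ids):
            rows.append((ident, self._ploidy[k], self._dam[k], self._sire[k]))
        for d, (dam, _y) in self._virtual.items():
            rows.append((d, "D", dam, FOUNDER))
        rows.sort(key=lambda t: t[0])  # ids are issued parents-first
        return rows


def gene_drop_kinship(
    pedigree: Iterable[tuple[int, str, int | str, int | str]],
    pair: tuple[int, int],
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte Carlo estimate of coancestry by dropping alleles.

    ``pedigree`` rows are (id, ploidy, dam, sire) in an order where
    parents precede offspring; founders (and environment drones) receive
    unique alleles.  Females draw one random dam allele plus the sire's
    single allele; drones draw one random dam allele.  Returns the
    estimated f for ``pair`` and its Monte Carlo standard error, with the
    per-replicate statistic being the exact IBD probability given that
    replicate's allele configuration.
    """
    rows = list(pedigree)
    order = [r[0] for r in rows]
    if len(set(order)) != len(order):
        raise ValueError("duplicate ids in pedigree")
    seen: set[int] = set()
    alleles: dict[int, np.ndarray] = {}
    counter = 0
    for ident, ploidy, dam, sire in rows:
        if (isinstance(dam, int) and dam not in seen) or (
            isinstance(sire, int) and sire not in seen
        ):
            raise ValueError("pedigree is not in parents-first order (or is cyclic)")
        if ploidy == "D":
            if isinstance(dam, int):
                da = alleles[dam]
                pick = rng.integers(0, 2, size=n_reps)
                alleles[ident] = da[np.arange(n_reps), pick]
            else:
                alleles[ident] = np.full(n_reps, counter, dtype=np.int64)
                counter += 1
        elif ploidy == "F":
            if isinstance(dam, int):
                da = alleles[dam]
                pick = rng.integers(0, 2, size=n_reps)
                maternal = da[np.arange(n_reps), pick]
            else:
                maternal = np.full(n_reps, counter, dtype=np.int64)
                counter += 1
            if isinstance(sire, int):
                paternal = np.asarray(alleles[sire])
                if paternal.ndim != 1:
                    raise ValueError("sire of a female must be haploid")
            else:
                paternal = np.full(n_reps, counter, dtype=np.int64)
                counter += 1
            alleles[ident] = np.stack([maternal, paternal], axis=1)
        else:
            raise ValueError(f"unknown ploidy flag: {ploidy!r}")
        seen.add(ident)

    i, j = pair
    ai, aj = alleles[i], alleles[j]
    if i == j:
        if ai.ndim == 1:
            stat = np.ones(n_reps)
        else:
            stat = 0.5 * (1.0 + (ai[:, 0] == ai[:, 1]).astype(float))
    else:
        ai2 = ai[:, None] if ai.ndim == 1 else ai
        aj2 = aj[:, None] if aj.ndim == 1 else aj
        eq = (ai2[:, :, None] == aj2[:, None, :]).astype(float)
        stat = eq.mean(axis=(1, 2))
    est = float(stat.mean())
    se = float(stat.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return est, se
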