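"""Annual cycle: demography, winter culls, selection and mating rules."""

import numpy as np
import pytest

from hivesim import (
    BVPair,
    GeneticSetup,
    KinshipTable,
    QueenRecord,
    ReplicateFailure,
    SETUPS,
    SchemeConfig,
    run_replicate,
    winter_cull,
)
from hivesim.scheme import (
    assign_matings,
    phenotype_colonies,
    produce_generation,
    select_breeding_queens,
    select_dpq,
)


def make_queen(qid, line=0, bv=(0.0, 0.0), f=0.0, dam="founder", year=0):
    return QueenRecord(
        id=qid, birth_year=year, dam_id=dam, sire_drone_id="founder",
        bv=BVPair(*bv), inbreeding=f, line_id=line,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- configuration --------------------------------------------------------


def test_default_demography_counts():
    cfg = SchemeConfig()
    assert cfg.n_candidates == 108  # 144 queen colonies, 25% first-winter loss
    assert cfg.n_pdpq_after_first_winter == 162  # 216 pDPQ, 25% loss
    assert cfg.n_pdpq_after_second_winter == 108  # a further third lost
    with pytest.raises(ValueError):
        SchemeConfig(selection_strategy="tournament")
    with pytest.raises(ValueError):
        SchemeConfig(first_winter_survival=0.0)


# -- winter mortality -----------------------------------------------------


def test_winter_cull_fixed_count(rng):
    ids = list(range(144))
    out = winter_cull(ids, 108, rng)
    assert len(out) == 108
    assert set(out) <= set(ids)
    assert winter_cull(ids, 144, rng) == ids
    with pytest.raises(ValueError):
        winter_cull(ids, 145, rng)


def test_winter_cull_is_uniform(rng):
    ids = list(range(8))
    hits = np.zeros(8)
    for _ in range(2000):
        for i in winter_cull(ids, 4, rng):
            hits[i] += 1
    assert hits.min() > 0.9 * hits.max()  # roughly uniform survival odds


# -- breeding queen selection ---------------------------------------------


def test_mass_selection_takes_overall_best(rng):
    perfs = [5, 1, 9, 3, 8, 7, 2, 6]
    colonies = [(make_queen(i), float(p)) for i, p in enumerate(perfs)]
    chosen = select_breeding_queens(colonies, "mass", rng)
    assert {q.id for q in chosen} == {0, 2, 4, 5, 7, 3}  # six largest


def test_within_line_selection_takes_best_per_line(rng):
    colonies = []
    for line in range(6):
        for k in range(3):
            qid = 10 * line + k
            colonies.append((make_queen(qid, line=line), float(line + 10 * k)))
    chosen = select_breeding_queens(colonies, "within_line", rng, lines=range(6))
    assert len(chosen) == 6
    assert sorted(q.line_id for q in chosen) == list(range(6))
    assert all(q.id % 10 == 2 for q in chosen)  # the k=2 member of each line


def test_extinct_line_is_replaced_by_splitting_a_survivor(rng):
    colonies = []
    for line in range(5):  # line 5 extinct
        for k in range(3):
            colonies.append((make_queen(100 * line + k, line=line), float(rng.normal())))
    chosen = select_breeding_queens(colonies, "within_line", rng, lines=range(6))
    assert len(chosen) == 6
    assert sorted(q.line_id for q in chosen) == list(range(6))  # registry refilled
    donors = [q for q in chosen if q.line_id == 5]
    assert len(donors) == 1  # exactly one queen relabelled into the freed slot


def test_too_few_candidates_is_a_replicate_failure(rng):
    colonies = [(make_queen(i), 1.0) for i in range(5)]
    with pytest.raises(ReplicateFailure):
        select_breeding_queens(colonies, "mass", rng)


# -- DPQ selection --------------------------------------------------------


def _families(rng, means, survivors_per_family=None):
    evaluated, surviving = {}, {}
    for f, mu in enumerate(means):
        group = [(make_queen(1000 * f + k, dam=f), mu + 0.01 * k) for k in range(10)]
        evaluated[f] = group
        n_surv = 10 if survivors_per_family is None else survivors_per_family[f]
        surviving[f] = group[:n_surv]
    return evaluated, surviving


def test_dpq_selection_takes_best_four_families_times_three(rng):
    evaluated, surviving = _families(rng, [1, 5, 3, 2, 6, 4])
    out = select_dpq(evaluated, surviving, rng)
    assert sorted(out) == [1, 2, 4, 5]  # the four best family means of six
    assert all(len(v) == 3 for v in out.values())
    for f, group in out.items():
        best = sorted((p for _, p in surviving[f]), reverse=True)[:3]
        assert sorted((q.id for q in group)) == sorted(
            q.id for q, p in surviving[f] if p in best
        )


def test_extinct_best_family_falls_through_to_next_rank(rng):
    evaluated, surviving = _families(rng, [1, 5, 3, 2, 6, 4], [10, 10, 10, 10, 0, 10])
    out = select_dpq(evaluated, surviving, rng)
    assert sorted(out) == [1, 2, 3, 5]  # family 4 extinct, 3 promoted


def test_family_with_two_survivors_supplies_both(rng):
    evaluated, surviving = _families(rng, [1, 5, 3, 2, 6, 4], [10, 2, 10, 10, 10, 10])
    out = select_dpq(evaluated, surviving, rng)
    assert len(out[1]) == 2
    evaluated, surviving = _families(rng, [1, 2, 3, 4, 5, 6], [0, 0, 0, 10, 10, 10])
    with pytest.raises(ReplicateFailure):
        select_dpq(evaluated, surviving, rng)


# -- mating ---------------------------------------------------------------


def test_environment_matings_are_unrelated_to_population(rng):
    setup = SETUPS[1]
    kin = KinshipTable()
    queens = []
    for i in range(4):
        fid = kin.add_founder_female()
        queens.append(make_queen(fid))
    assign_matings(queens, None, 8, rng, kin, setup, year=0)
    for q in queens:
        assert len(q.mate_drone_ids) == 8
        assert q.mate_bvs.shape == (8, 2)
        for d in q.mate_drone_ids[:2]:
            assert kin.coancestry(q.id, d) == 0.0


def test_dpq_matings_balance_families(rng):
    setup = SETUPS[1]
    kin = KinshipTable()
    queens = []
    for _ in range(360):
        fid = kin.add_founder_female()
        queens.append(make_queen(fid))
    dpq_by_family = {}
    for fam in range(4):
        group = []
        for _ in range(3):
            fid = kin.add_founder_female()
            group.append(make_queen(fid))
        dpq_by_family[fam] = group
    sources = assign_matings(queens, dpq_by_family, 1, rng, kin, setup, year=1)
    dpq_to_fam = {d.id: fam for fam, g in dpq_by_family.items() for d in g}
    counts = np.bincount([dpq_to_fam[s] for s in sources.values()], minlength=4)
    assert counts.tolist() == [90, 90, 90, 90]
    assert all(len(q.mate_drone_ids) == 1 for q in queens)
    with pytest.raises(ReplicateFailure):
        assign_matings(queens, {}, 1, rng, kin, setup, year=1)


# -- reproduction ---------------------------------------------------------


def _mated_founders(kin, setup, rng, n=6, nd=8):
    queens = []
    for i in range(n):
        fid = kin.add_founder_female()
        queens.append(make_queen(fid, line=i))
    assign_matings(queens, None, nd, rng, kin, setup, year=0)
    return queens


def test_generation_counts_and_line_inheritance(rng):
    setup = SETUPS[1]
    kin = KinshipTable()
    bqs = _mated_founders(kin, setup, rng)
    virgins, pdpqs = produce_generation(bqs, SchemeConfig(), kin, setup, rng, year=1)
    assert len(virgins) == 144 and len(pdpqs) == 216
    assert {q.line_id for q in virgins} == set(range(6))
    assert all(q.birth_year == 1 for q in virgins)
    # F recomputed from the kinship table matches the stored value
    for q in virgins[:10]:
        assert q.inbreeding == kin.inbreeding_of_cross(q.dam_id, q.sire_drone_id)


def test_zero_variance_parents_give_zero_daughters(rng):
    setup = GeneticSetup(0, 0, 0.0, 0)
    kin = KinshipTable()
    bqs = _mated_founders(kin, setup, rng)
    virgins, pdpqs = produce_generation(bqs, SchemeConfig(), kin, setup, rng, year=1)
    assert all(q.bv == BVPair(0.0, 0.0) for q in virgins + pdpqs)


def test_monoandrous_daughters_are_super_sisters(rng):
    setup = SETUPS[1]
    kin = KinshipTable()
    bqs = _mated_founders(kin, setup, rng, nd=1)
    cfg = SchemeConfig(n_drones_per_queen=1)
    virgins, _ = produce_generation(bqs, cfg, kin, setup, rng, year=1)
    sibs = [q for q in virgins if q.dam_id == bqs[0].id][:2]
    assert kin.relationship(sibs[0].id, sibs[1].id) == 0.75


def test_phenotype_decomposition(rng):
    setup = GeneticSetup(10, 10, 0.0, 0.0)  # no residual
    kin = KinshipTable()
    queens = _mated_founders(kin, setup, rng, n=3, nd=4)
    perfs = phenotype_colonies(queens, setup, rng)
    for q, p in zip(queens, perfs):
        assert p == pytest.approx(q.bv.bv_mat + 0.5 * q.bv.bv_dir + q.mate_bvs[:, 0].mean())


# -- full replicate -------------------------------------------------------


def test_replicate_timeline_and_inbreeding_onset():
    """Cohorts mated to environment drones (years 1-3) are non-inbred; the
    population closes on the sire path in year 4 and F rises afterwards."""
    cfg = SchemeConfig(selection_strategy="mass", n_drones_per_queen=8, total_years=10)
    out = run_replicate(SETUPS[1], cfg, 99)
    assert out["mean_F"][:3].tolist() == [0.0, 0.0, 0.0]
    assert np.all(np.isfinite(np.column_stack(list(out.values()))))
    assert out["mean_F"][4:].min() > 0.0
    assert out["mean_F"][9] > out["mean_F"][4]


def test_replicate_reproducible_given_seed():
    cfg = SchemeConfig(total_years=6)
    a = run_replicate(SETUPS[3], cfg, 5)
    b = run_replicate(SETUPS[3], cfg, 5)
    for k in a:
        assert np.array_equal(a[k], b[k])
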