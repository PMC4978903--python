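import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ciliamap import (ContractError, GenotypeState, MacronuclearState,
                      MicronuclearGenotype, Site, assort, call_genotypes,
                      cross, develop_macronucleus, make_truth,
                      pool_and_sequence, read_truth, select_assortants,
                      simulate_cross, simulate_mutagenesis, write_truth)
from ciliamap.simulate import (CrossPlan, ReadCounts, SequencingModel,
                               _assort_matrix)


def _single_site_genotype(dosage: int) -> MicronuclearGenotype:
    sites = (Site("chr1", 100, "A", "T"),)
    alleles = {0: [0, 0], 1: [0, 1], 2: [1, 1]}[dosage]
    return MicronuclearGenotype(sites, np.array([alleles], dtype=np.int8))


# ---------------------------------------------------------------------------
# Mutagenesis


def test_zero_mutation_rate_plants_only_the_causal_site(genome, rng):
    plan = CrossPlan(mutation_rate=0.0)
    parent, background = simulate_mutagenesis(genome, plan, rng)
    assert background == ()
    assert parent.sites == (genome.causal_site,)
    assert parent.dosage().tolist() == [1]


def test_mutagenesis_count_matches_poisson_mean(genome):
    rate, reps = 200.0, 1000
    rng = np.random.default_rng(7)
    plan = CrossPlan(mutation_rate=rate)
    counts = [len(simulate_mutagenesis(genome, plan, rng)[1]) for _ in range(reps)]
    se = np.sqrt(rate / reps)  # Poisson moment oracle: var == mean
    assert abs(np.mean(counts) - rate) < 3 * se


def test_all_planted_sites_heterozygous_and_match_genome(genome, rng):
    parent, background = simulate_mutagenesis(genome, CrossPlan(mutation_rate=150), rng)
    assert (parent.dosage() == 1).all()
    for site in background:
        assert genome.sequences[site.chrom][site.pos - 1] == site.ref
        assert site.alt != site.ref
    assert len({(s.chrom, s.pos) for s in parent.sites}) == len(parent.sites)


# ---------------------------------------------------------------------------
# Crosses


def test_het_by_het_segregates_one_quarter_homozygous_mutant(rng):
    n = 10_000
    progeny = cross(_single_site_genotype(1), _single_site_genotype(1), n, rng)
    frac = np.mean([g.dosage()[0] == 2 for g in progeny])
    se = np.sqrt(0.25 * 0.75 / n)
    assert abs(frac - 0.25) < 3 * se


def test_hom_by_hom_breeds_true(rng):
    progeny = cross(_single_site_genotype(2), _single_site_genotype(2), 50, rng)
    assert all(g.dosage()[0] == 2 for g in progeny)


def test_het_by_homozygous_wildtype_gamete_table(rng):
    n = 10_000
    progeny = cross(_single_site_genotype(1), _single_site_genotype(0), n, rng)
    dosage = np.array([g.dosage()[0] for g in progeny])
    assert (dosage == 2).sum() == 0  # no mutant homozygotes possible
    se = np.sqrt(0.5 * 0.5 / n)
    assert abs((dosage == 1).mean() - 0.5) < 3 * se


def test_cross_rejects_mismatched_site_sets(rng):
    other = MicronuclearGenotype((Site("chr2", 5, "G", "C"),),
                                 np.array([[0, 0]], dtype=np.int8))
    with pytest.raises(ContractError):
        cross(_single_site_genotype(1), other, 5, rng)


# ---------------------------------------------------------------------------
# Macronuclear development and assortment


def test_macronucleus_initialization_rounding():
    mac = develop_macronucleus(_single_site_genotype(1), ploidy=45)
    assert mac.alt_copies[0] == 23  # mutant allele takes the ceil share
    assert develop_macronucleus(_single_site_genotype(2), 45).alt_copies[0] == 45
    assert develop_macronucleus(_single_site_genotype(0), 45).alt_copies[0] == 0


@given(dosage=st.lists(st.integers(0, 2), min_size=1, max_size=30),
       ploidy=st.integers(2, 90),
       divisions=st.integers(0, 8))
def test_copy_number_conserved_through_development_and_assortment(dosage, ploidy, divisions):
    sites = tuple(Site("chr1", i + 1, "A", "T") for i in range(len(dosage)))
    alleles = np.array([{0: [0, 0], 1: [0, 1], 2: [1, 1]}[d] for d in dosage], dtype=np.int8)
    mac = develop_macronucleus(MicronuclearGenotype(sites, alleles), ploidy)
    assorted = assort(mac, divisions, np.random.default_rng(0))
    assert ((0 <= assorted.alt_copies) & (assorted.alt_copies <= ploidy)).all()
    assert assorted.ploidy == ploidy  # copies always sum to ploidy per site


def test_homozygous_states_are_absorbing(rng):
    sites = (Site("chr1", 1, "A", "T"), Site("chr1", 2, "C", "G"))
    state = MacronuclearState(sites, np.array([45, 0]), 45)
    out = assort(state, 200, rng)
    assert out.alt_copies.tolist() == [45, 0]


def test_fixation_probability_equals_initial_copy_fraction():
    # Optional-stopping of the allele-fraction martingale: P(fix) = a0/ploidy.
    rng = np.random.default_rng(11)
    ploidy, a0, reps = 45, 22, 10_000
    copies = np.full(reps, a0, dtype=np.int64)
    for _ in range(3000):
        live = (copies != 0) & (copies != ploidy)
        if not live.any():
            break
        copies[live] = rng.hypergeometric(
            2 * copies[live], 2 * (ploidy - copies[live]), ploidy)
    assert ((copies == 0) | (copies == ploidy)).all()
    p = a0 / ploidy
    se = np.sqrt(p * (1 - p) / reps)
    assert abs((copies == ploidy).mean() - p) < 3 * se


def test_allele_fraction_is_a_martingale():
    rng = np.random.default_rng(13)
    ploidy, a0, reps, divisions = 45, 23, 20_000, 25
    copies = _assort_matrix(np.full(reps, a0), ploidy, divisions, rng)
    frac = copies / ploidy
    se = frac.std(ddof=1) / np.sqrt(reps)
    assert abs(frac.mean() - a0 / ploidy) < 3 * se


def test_single_division_variance_matches_hypergeometric():
    rng = np.random.default_rng(17)
    ploidy, a = 45, 22
    reps = 200_000
    copies = _assort_matrix(np.full(reps, a), ploidy, 1, rng)
    N, K, n = 2 * ploidy, 2 * a, ploidy
    expected = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    assert copies.var(ddof=1) == pytest.approx(expected, rel=0.05)


def test_select_assortants_threshold_is_zero_wildtype_copies():
    site = Site("chr1", 100, "A", "T")
    full = MacronuclearState((site,), np.array([45]), 45, clone_id=0)
    almost = MacronuclearState((site,), np.array([44]), 45, clone_id=1)
    none = MacronuclearState((site,), np.array([0]), 45, clone_id=2)
    selected = select_assortants([almost, full, none], site)
    assert [c.clone_id for c in selected] == [0]


def test_selection_grows_with_divisions():
    site = Site("chr1", 100, "A", "T")
    mics = [_single_site_genotype(1) for _ in range(4000)]

    def count(divisions, seed):
        rng = np.random.default_rng(seed)
        macs = [develop_macronucleus(m, 45) for m in mics]
        mat = _assort_matrix(np.stack([m.alt_copies for m in macs]), 45, divisions, rng)
        return int((mat[:, 0] == 45).sum())

    assert count(20, 3) < count(80, 3) < count(300, 3)


# ---------------------------------------------------------------------------
# Sequencing and calling


def _uniform_pool(alt_copies: int, n_sites: int = 1, n_clones: int = 25):
    sites = tuple(Site("chr1", i + 1, "A", "T") for i in range(n_sites))
    return [MacronuclearState(sites, np.full(n_sites, alt_copies), 45, clone_id=i)
            for i in range(n_clones)]


def test_error_free_fully_mutant_pool_yields_only_alt_reads(rng):
    pool = _uniform_pool(45)
    refs = {"parental": MacronuclearState(pool[0].sites, np.array([0]), 45)}
    model = SequencingModel(coverage={"mutant_pool": 70, "parental": 256}, base_error=0.0)
    counts = pool_and_sequence(pool, refs, model, rng)
    mut = counts.samples.index("mutant_pool")
    assert counts.ref_counts[mut, 0] == 0 and counts.other_counts[mut, 0] == 0
    assert counts.alt_counts[mut, 0] == counts.depth[mut, 0]
    par = counts.samples.index("parental")
    assert counts.alt_counts[par, 0] == 0  # all-ref apart from (disabled) errors


def test_sequencing_depth_matches_poisson_mean(rng):
    n_sites = 1000
    pool = _uniform_pool(45, n_sites=n_sites)
    refs = {"parental": MacronuclearState(pool[0].sites, np.zeros(n_sites, dtype=int), 45)}
    model = SequencingModel(coverage={"mutant_pool": 70, "parental": 256})
    counts = pool_and_sequence(pool, refs, model, rng)
    mut = counts.samples.index("mutant_pool")
    se = np.sqrt(70 / n_sites)
    assert abs(counts.depth[mut].mean() - 70) < 3 * se


def test_empty_pool_rejected(rng):
    with pytest.raises(ContractError):
        pool_and_sequence([], {}, SequencingModel(), rng)


def test_zero_depth_is_missing_and_pure_hom_alt_called():
    sites = (Site("chr1", 1, "A", "T"),)
    counts = ReadCounts(sites, ("mutant_pool", "parental"),
                        depth=np.array([[70], [0]]),
                        ref_counts=np.array([[0], [0]]),
                        alt_counts=np.array([[70], [0]]),
                        other_counts=np.array([[0], [0]]))
    model = SequencingModel(coverage={"mutant_pool": 70, "parental": 256})
    (rec,) = call_genotypes(counts, model)
    assert rec.calls["mutant_pool"].state is GenotypeState.HOM_ALT
    assert rec.calls["parental"].state is GenotypeState.MISSING


def test_all_reference_sites_not_emitted():
    sites = (Site("chr1", 1, "A", "T"),)
    counts = ReadCounts(sites, ("mutant_pool",),
                        depth=np.array([[70]]), ref_counts=np.array([[70]]),
                        alt_counts=np.array([[0]]), other_counts=np.array([[0]]))
    assert call_genotypes(counts, SequencingModel(coverage={"mutant_pool": 70})) == []


def test_hom_alt_call_rate_matches_binomial_tail():
    # Pool of 24 fully mutant clones + 1 heterozygous MAC (23/45 mutant copies):
    # expected alt read fraction p = (24 + 23/45)/25; at fixed depth 70 and
    # hom_fraction 0.9 a HOM_ALT call needs >= ceil(0.9*70) = 63 alt reads.
    p = (24 + 23 / 45) / 25
    depth, thresh = 70, 63
    expected = stats.binom.sf(thresh - 1, depth, p)
    rng = np.random.default_rng(23)
    n_sites = 20_000
    alt = rng.binomial(depth, p, size=n_sites)
    sites = tuple(Site("chr1", i + 1, "A", "T") for i in range(n_sites))
    counts = ReadCounts(sites, ("mutant_pool",),
                        depth=np.full((1, n_sites), depth),
                        ref_counts=(depth - alt)[None, :],
                        alt_counts=alt[None, :],
                        other_counts=np.zeros((1, n_sites), dtype=int))
    model = SequencingModel(coverage={"mutant_pool": 70}, hom_fraction=0.9)
    records = call_genotypes(counts, model)
    n_hom_alt = sum(r.calls["mutant_pool"].state is GenotypeState.HOM_ALT
                    for r in records)
    se = np.sqrt(expected * (1 - expected) / n_sites)
    assert abs(n_hom_alt / n_sites - expected) < 3 * se


def test_noise_free_high_coverage_recovers_pooled_state(rng):
    # With no errors, min_depth 1 and coverage >= 10x ploidy, a fully
    # assorted pool is called HOM_ALT wherever fixed mutant, HOM_REF (not
    # emitted) wherever fixed wild type.
    sites = tuple(Site("chr1", i + 1, "A", "T") for i in range(20))
    fixed = np.array([45 if i % 2 == 0 else 0 for i in range(20)])
    pool = [MacronuclearState(sites, fixed, 45, clone_id=i) for i in range(25)]
    refs = {"parental": MacronuclearState(sites, np.zeros(20, dtype=int), 45)}
    model = SequencingModel(coverage={"mutant_pool": 450, "parental": 450},
                            base_error=0.0, min_depth=1)
    records = call_genotypes(pool_and_sequence(pool, refs, model, rng), model)
    called = {(r.chrom, r.pos): r.calls["mutant_pool"].state for r in records}
    for i, site in enumerate(sites):
        if fixed[i] == 45:
            assert called[(site.chrom, site.pos)] is GenotypeState.HOM_ALT
        else:
            assert (site.chrom, site.pos) not in called


# ---------------------------------------------------------------------------
# Truth ledger and end-to-end determinism


def test_truth_ledger_contents_and_round_trip(tmp_path, genome, rng):
    plan = CrossPlan(mutation_rate=30)
    parent, background = simulate_mutagenesis(genome, plan, rng)
    clones = [(i, parent) for i in range(3)]
    truth = make_truth(genome, background, parent.sites, clones)
    assert truth.causal == genome.causal_site
    assert len(truth.background) == len(background)
    path = write_truth(truth, tmp_path / "truth.tsv")
    back = read_truth(path)
    assert back.sites == truth.sites
    assert back.causal == truth.causal
    assert back.clone_ids == truth.clone_ids
    assert (back.clone_dosage == truth.clone_dosage).all()


def test_simulate_cross_is_deterministic_per_seed():
    a = simulate_cross(seed=5)
    b = simulate_cross(seed=5)
    assert len(a.records) == len(b.records)
    for ra, rb in zip(a.records, b.records):
        assert (ra.chrom, ra.pos, ra.ref_allele, ra.alt_alleles) == \
               (rb.chrom, rb.pos, rb.ref_allele, rb.alt_alleles)
        assert all(ra.calls[s] == rb.calls[s] for s in a.samples)
    assert a.n_selected == b.n_selected


def test_simulated_causal_site_always_in_ledger():
    sim = simulate_cross(seed=9)
    assert sim.truth.causal == sim.genome.causal_site
    assert sim.truth.causal in sim.truth.sites
    assert len(sim.truth.background) == len(sim.truth.sites) - 1
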