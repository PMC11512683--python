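import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ampliclone as ac
from ampliclone.calling import (HOM_MUT, MUT, UNDETECTED, UNDETERMINED, WT,
                                _fit_beta_moments)
from ampliclone.errors import (ContractError, EstimationError, StructureError)


class TestScvaf:
    @pytest.mark.parametrize("variant,cov,expected",
                             [(0, 100, 0.0), (50, 100, 0.5), (3, 60, 0.05)])
    def test_exact_ratio(self, variant, cov, expected):
        assert ac.compute_scvaf(variant, cov) == expected

    def test_zero_coverage_is_a_contract_violation(self):
        with pytest.raises(ContractError):
            ac.compute_scvaf(0, 0)
        with pytest.raises(ContractError):
            ac.compute_scvaf(10, 5)


class TestDeriveThresholds:
    def test_worked_example_moments(self, tet2_thresholds):
        """Control mean 0.000719 and SD 0.000472 give a WT cutoff of
        mean + 3 SD and a mutant cutoff 0.01 above it (the printed pair is
        0.002136 / 0.012136 from unrounded source data; recomputation from
        the rounded moments agrees to rounding)."""
        t = tet2_thresholds
        assert t.wt_threshold == pytest.approx(0.002136, abs=2e-6)
        assert t.mutant_threshold == pytest.approx(0.012136, abs=2e-6)
        assert t.hom_mutant_threshold == pytest.approx(1 - t.mutant_threshold)

    def test_zero_noise_locus(self):
        t = ac.derive_thresholds([0.0] * 40, "clean")
        assert t.wt_threshold == 0.0
        assert t.mutant_threshold == 0.01
        assert t.hom_mutant_threshold == 0.99

    def test_moments_match_independent_direct_pass(self):
        """On 500 beta-distributed control scVAFs the thresholds equal
        mean + 3*SD (+0.01) computed by a direct, independent pass."""
        rng = np.random.default_rng(11)
        x = rng.beta(2, 2000, size=500)
        t = ac.derive_thresholds(x, "beta")
        # independent brute-force moments (explicit formulas, not numpy stats)
        m = sum(x) / len(x)
        sd = (sum((v - m) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert t.wt_threshold == pytest.approx(m + 3 * sd, rel=1e-12)
        assert t.mutant_threshold == pytest.approx(m + 3 * sd + 0.01, rel=1e-12)

    def test_too_few_control_cells_names_amplicon(self):
        with pytest.raises(EstimationError, match="JAK2"):
            ac.derive_thresholds([0.0] * 5, "JAK2_gDNA")


class TestCallAmplicon:
    def test_low_coverage_gdna_undetected(self, tet2_thresholds):
        call = ac.call_amplicon("c", "a", 15, 5, "gDNA", tet2_thresholds)
        assert call.call == UNDETECTED

    def test_cdna_coverage_floor_is_30(self, tet2_thresholds):
        assert ac.call_amplicon("c", "a", 26, 4, "cDNA",
                                tet2_thresholds).call != UNDETECTED
        assert ac.call_amplicon("c", "a", 26, 4, "gDNA",
                                tet2_thresholds).call == UNDETECTED

    def test_above_threshold_but_few_mutant_reads_is_undetermined(
            self, tet2_thresholds):
        call = ac.call_amplicon("c", "a", 392, 8, "gDNA", tet2_thresholds)
        assert call.scvaf > tet2_thresholds.mutant_threshold
        assert call.call == UNDETERMINED
        assert call.reason == "insufficient_mutant_reads"

    def test_mid_range_heterozygote(self, tet2_thresholds):
        assert ac.call_amplicon("c", "a", 50, 50, "gDNA",
                                tet2_thresholds).call == MUT

    def test_hom_mutant_above_mirrored_threshold(self, tet2_thresholds):
        call = ac.call_amplicon("c", "a", 1, 199, "gDNA", tet2_thresholds)
        assert call.scvaf >= 1 - tet2_thresholds.mutant_threshold
        assert call.call == HOM_MUT

    def test_exact_wt_boundary_is_undetermined(self):
        """The WT comparison is strict: a cell sitting exactly on the WT
        cutoff is conservatively undetermined."""
        t = ac.thresholds_from_moments(0.04, 0.02, "b")  # wt cutoff 0.1
        assert t.wt_threshold == pytest.approx(0.1)
        call = ac.call_amplicon("c", "a", 90, 10, "gDNA", t)
        assert call.call == UNDETERMINED

    def test_hemizygous_locus_never_hom(self, tet2_thresholds):
        call = ac.call_amplicon("c", "a", 1, 199, "gDNA", tet2_thresholds,
                                ploidy="hemizygous")
        assert call.call == MUT


def oracle_call(coverage, alt, analyte, thr, cfg):
    """Independent hand-enumerated decision table for one observation."""
    min_cov = 50 if analyte == "gDNA" else 30
    if coverage < min_cov:
        return UNDETECTED
    scvaf = alt / coverage
    if scvaf < thr.wt_threshold:
        return WT
    if scvaf < thr.mutant_threshold:
        return UNDETERMINED
    if alt < cfg.min_mutant_reads:
        return UNDETERMINED
    if scvaf >= thr.hom_mutant_threshold:
        return HOM_MUT
    return MUT


def test_decision_table_equivalence(tet2_thresholds, default_cfg):
    """call_amplicon agrees with an exhaustively enumerated truth table over
    coverage, scVAF and mutant-read bands in both analytes."""
    thr = tet2_thresholds
    coverages = [0, 10, 29, 30, 49, 50, 200, 2000]
    scvaf_bands = [0.0, thr.wt_threshold / 2, thr.wt_threshold,
                   (thr.wt_threshold + thr.mutant_threshold) / 2,
                   thr.mutant_threshold, 0.05, 0.5,
                   thr.hom_mutant_threshold, 0.999, 1.0]
    n_cases = 0
    for analyte in ("gDNA", "cDNA"):
        for cov in coverages:
            for s in scvaf_bands:
                alt = round(s * cov)
                if not 0 <= alt <= cov:
                    continue
                got = ac.call_amplicon("c", "a", cov - alt, alt, analyte,
                                       thr, default_cfg)
                assert got.call == oracle_call(cov, alt, analyte, thr,
                                               default_cfg), \
                    (analyte, cov, alt)
                n_cases += 1
    assert n_cases >= 60


class TestConsensus:
    @pytest.mark.parametrize("gdna,cdna,expected", [
        (WT, UNDETECTED, WT),            # gDNA WT, cDNA uninformative
        (UNDETECTED, WT, UNDETERMINED),  # cDNA WT alone cannot call WT
        (WT, MUT, MUT),                  # mutant in either analyte
        (WT, WT, WT),
        (MUT, WT, MUT),
        (HOM_MUT, UNDETECTED, MUT),      # hom counts as mutant downstream
        (WT, None, WT),                  # cDNA amplicon absent
        (UNDETERMINED, UNDETERMINED, UNDETERMINED),
        (UNDETECTED, None, UNDETERMINED),
    ])
    def test_rule_table(self, gdna, cdna, expected):
        assert ac.consensus_call(gdna, cdna).consensus == expected

    def test_totality_over_all_state_pairs(self):
        """The consensus is defined for every (gDNA, cDNA) state pair,
        including an absent cDNA amplicon."""
        states = [WT, MUT, HOM_MUT, UNDETERMINED, UNDETECTED]
        for g in states:
            for c in states + [None]:
                out = ac.consensus_call(g, c).consensus
                assert out in (WT, MUT, UNDETERMINED)

    def test_mismatched_cells_rejected(self):
        a = ac.AmpliconCall("c1", "x", 0.5, 100, 50, MUT, "r")
        b = ac.AmpliconCall("c2", "y", 0.5, 100, 50, WT, "r")
        with pytest.raises(ContractError):
            ac.consensus_call(a, b)


def test_threshold_monotonicity(sim_dataset):
    """Raising the SD multiplier or the mutant margin never increases the
    number of mutant calls on a fixed dataset."""
    _, result, ds = sim_dataset
    n_mut_prev = None
    for mult, margin in [(2.0, 0.005), (3.0, 0.01), (5.0, 0.03)]:
        cfg = ac.RunConfig(sd_multiplier=mult, mutant_margin=margin)
        thresholds = ac.derive_all_thresholds(ds, cfg)
        calls = ac.call_dataset(ds, thresholds, cfg)
        n_mut = int((calls["consensus"] == MUT).sum())
        if n_mut_prev is not None:
            assert n_mut <= n_mut_prev
        n_mut_prev = n_mut


class TestFpValidation:
    def test_all_zero_controls_give_zero_fp(self, tet2_thresholds):
        v = ac.validate_fp_probability([0.0] * 50, tet2_thresholds)
        assert v.fp_probability == 0.0
        assert v.beta_params is None

    def test_printed_moments_within_reported_bound(self, tet2_thresholds):
        """A beta fitted by method of moments to the printed control moments
        has essentially no mass beyond the mutant threshold."""
        tail = ac.beta_tail_probability(0.000719, 0.000472,
                                        tet2_thresholds.mutant_threshold)
        assert 0 <= tail <= 0.006

    def test_bootstrap_tails_match_monte_carlo_oracle(self):
        """Replicate tail probabilities agree with an independent Monte-Carlo
        tail estimate (1e6 draws from the full-sample fit) within three
        bootstrap SEs."""
        rng = np.random.default_rng(3)
        x = rng.beta(2, 2000, size=400)
        cfg = ac.RunConfig(bootstrap_reps=300, rng_seed=3)
        thr = ac.ThresholdSet("b", 0.01, 0.02, 0.98)
        v = ac.validate_fp_probability(x, thr, cfg)
        a, b = v.beta_params
        mc = float((np.random.default_rng(4).beta(a, b, 10 ** 6) > 0.02).mean())
        tails = np.asarray(v.replicate_tails)
        se = tails.std(ddof=1)
        assert abs(v.fp_probability - mc) <= 3 * se + 1e-4
        assert v.fp_range[0] <= v.fp_probability <= v.fp_range[1]

    def test_type_one_error_on_simulated_wt_cells(self, tet2_thresholds):
        """Cells simulated from the fitted control beta are called mutant no
        more often than the validated false-positive probability allows."""
        a, b = _fit_beta_moments(
            np.random.default_rng(0).beta(2.3, 3200, size=500))
        rng = np.random.default_rng(9)
        n = 20000
        scvafs = rng.beta(a, b, size=n)
        fp = float(stats.beta.sf(tet2_thresholds.mutant_threshold, a, b))
        called_mut = (scvafs >= tet2_thresholds.mutant_threshold)
        se = np.sqrt(max(fp, 1 / n) * (1 - fp) / n)
        assert called_mut.mean() <= fp + 3 * se


class TestMinimaThresholds:
    @staticmethod
    def trimodal_sample(rng, n=3000, w=(0.2, 0.6, 0.2), het_a=2.2,
                        noise_m=0.004, noise_a=2.0):
        comps = rng.choice(3, p=w, size=n)
        b = noise_a * (1 - noise_m) / noise_m
        return np.where(
            comps == 0, rng.beta(noise_a, b, n),
            np.where(comps == 1, rng.beta(het_a, het_a, n),
                     1 - rng.beta(noise_a, b, n)))

    def test_minima_near_observed_locations(self):
        """A trimodal scVAF mixture (noise near 0, skewed heterozygotes,
        mirrored noise near 1) yields interior minima near 0.15 and 0.85."""
        x = self.trimodal_sample(np.random.default_rng(7))
        t = ac.minima_thresholds(x, "snp")
        assert t.mutant_threshold == pytest.approx(0.15, abs=0.05)
        assert t.hom_mutant_threshold == pytest.approx(0.85, abs=0.05)
        assert t.strategy == "distribution_minima"

    def test_unimodal_sample_raises_structure_error(self):
        x = np.random.default_rng(1).beta(5, 5, size=1000)
        with pytest.raises(StructureError):
            ac.minima_thresholds(x)

    def test_minima_match_grid_search_oracle(self):
        """The reported minima equal an exhaustive grid search over the same
        KDE curve at step 0.001."""
        x = self.trimodal_sample(np.random.default_rng(42))
        t = ac.minima_thresholds(x, grid_points=1001)
        grid = np.linspace(0, 1, 1001)
        dens = stats.gaussian_kde(x, bw_method="silverman")(grid)
        # oracle: global minimum between the outer peaks, split at the
        # central (heterozygous) peak
        peak_mid = grid[np.argmax(np.where((grid > 0.3) & (grid < 0.7),
                                           dens, -np.inf))]
        lo_zone = (grid > 0.01) & (grid < peak_mid)
        hi_zone = (grid > peak_mid) & (grid < 0.99)
        lo = grid[lo_zone][np.argmin(dens[lo_zone])]
        hi = grid[hi_zone][np.argmin(dens[hi_zone])]
        assert t.mutant_threshold == pytest.approx(lo, abs=1e-9)
        assert t.hom_mutant_threshold == pytest.approx(hi, abs=1e-9)

    def test_minima_strategy_expands_undetermined_set(self, sim_dataset,
                                                      sim_calls):
        """When the minima cutoffs exceed the control-derived cutoffs, the
        minima strategy turns a superset of cells undetermined (low-scVAF
        mutant cells are reassigned)."""
        _, result, ds = sim_dataset
        thresholds, calls = sim_calls
        minima_thr = {
            amp: ac.calling._minima_thresholdset(
                amp, 0.15, 0.85, wt_threshold=thresholds[amp].wt_threshold)
            for amp in thresholds
        }
        calls_min = ac.call_dataset(ds, minima_thr)
        key = ["cell_id", "mutation_id"]
        merged = calls.merge(calls_min, on=key, suffixes=("_ctrl", "_min"))
        und_ctrl = set(map(tuple, merged.loc[
            merged["consensus_ctrl"] == UNDETERMINED, key].to_numpy()))
        und_min = set(map(tuple, merged.loc[
            merged["consensus_min"] == UNDETERMINED, key].to_numpy()))
        assert und_ctrl <= und_min
        assert len(und_min) > len(und_ctrl)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10 ** 6))
def test_threshold_invariants_hold_for_random_controls(seed):
    """Derived thresholds always satisfy the ordering invariant
    0 <= wt < mutant < hom <= 1 for realistic control noise."""
    rng = np.random.default_rng(seed)
    x = rng.beta(rng.uniform(1, 5), rng.uniform(100, 10000), size=60)
    t = ac.derive_thresholds(x, "r")
    assert 0 <= t.wt_threshold < t.mutant_threshold < t.hom_mutant_threshold <= 1
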