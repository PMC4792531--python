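"""Birth-death gene family model: kernel, likelihood, lambda estimation."""

import numpy as np
import pytest
from scipy.linalg import expm

from ncrphylo.gainloss import (
    FamilyProfile,
    GainLossModel,
    estimate_lambda,
    expansions_contractions,
    family_loglik,
    gain_loss_summary,
    make_ultrametric,
    profiles_loglik,
    root_presence_filter,
    transition_matrix,
    transition_prob,
)
from ncrphylo.tree import parse_species_tree
from ncrphylo.synthetic import SimulationConfig, simulate_profiles

from oracles import oracle_family_likelihood


def bd_expm(lam, t, n_states=200):
    """Truncated generator-exponential of the equal-rate linear BD chain."""
    q = np.zeros((n_states + 1, n_states + 1))
    for s in range(1, n_states + 1):
        q[s, s - 1] += lam * s
        if s < n_states:
            q[s, s + 1] += lam * s
            q[s, s] -= 2 * lam * s
        else:
            q[s, s] -= lam * s
    return expm(q * t)


@pytest.fixture(scope="module")
def tree3():
    tree = parse_species_tree("((A:10,B:10)AB:20,C:30)root;")
    tree.prepare()
    return tree


class TestKernel:
    def test_zero_time_is_identity(self):
        for s in range(1, 6):
            for c in range(8):
                assert transition_prob(s, c, 0.0, 0.01) == (1.0 if c == s else 0.0)

    def test_extinction_probability_closed_form(self):
        lam, t = 0.004, 25.0
        alpha = lam * t / (1 + lam * t)
        assert transition_prob(1, 0, t, lam) == pytest.approx(alpha)

    def test_extinct_family_stays_extinct(self):
        assert transition_prob(0, 0, 17.0, 0.01) == 1.0
        assert transition_prob(0, 3, 17.0, 0.01) == 0.0

    def test_matches_matrix_exponential_oracle(self):
        """Kernel equals the linear birth-death transition function (s,c <= 5)."""
        for lam, t in [(0.002, 90.0), (0.01, 30.0), (0.005, 160.0)]:
            p = bd_expm(lam, t)
            for s in range(6):
                for c in range(6):
                    assert transition_prob(s, c, t, lam) == pytest.approx(
                        p[s, c], abs=1e-6
                    )

    def test_alpha_cap(self):
        with pytest.raises(ValueError, match="alpha"):
            transition_prob(1, 1, 1000.0, 1.0)

    def test_rows_sum_to_one_in_the_limit(self):
        """Sum over c approaches 1; >= 1 - 1e-6 by c = 50 for small alpha."""
        lam, t = 0.003, 100.0  # alpha = 0.23
        for s in range(1, 6):
            total = sum(transition_prob(s, c, t, lam) for c in range(51))
            assert total >= 1 - 1e-6

    def test_matrix_agrees_with_scalar(self):
        m = transition_matrix(12, 45.0, 0.004)
        for s in range(13):
            for c in range(13):
                assert m[s, c] == pytest.approx(
                    transition_prob(s, c, 45.0, 0.004), abs=1e-12
                )


class TestUltrametric:
    def test_age_subtraction(self):
        tree = parse_species_tree("((A,B)AB,C)root;")
        ages = {"root": 100, "AB": 60, "A": 0, "B": 0, "C": 0}
        out = make_ultrametric(tree, ages)
        lengths = {
            n.label: n.length for n in out.postorder() if n.parent is not None
        }
        assert lengths == {"AB": 40, "A": 60, "B": 60, "C": 100}

    def test_equal_ages_error(self):
        tree = parse_species_tree("((A,B)AB,C)root;")
        ages = {"root": 100, "AB": 100, "A": 0, "B": 0, "C": 0}
        with pytest.raises(ValueError):
            make_ultrametric(tree, ages)

    def test_random_ages_ultrametric_before_rounding(self, rng):
        tree = parse_species_tree("(((A,B)AB,C)ABC,D)root;")
        for _ in range(20):
            inner = np.sort(rng.uniform(10, 200, size=3))
            ages = {
                "A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0,
                "AB": float(inner[0]), "ABC": float(inner[1]), "root": float(inner[2]),
            }
            out = make_ultrametric(tree, ages)
            # pre-rounding root-to-leaf sums all equal the root age
            for leaf in out.leaves():
                total, node = 0.0, leaf
                while node.parent is not None:
                    # recover unrounded length from ages
                    total += ages[node.parent.label] - ages[node.label]
                    node = node.parent
                assert total == pytest.approx(ages["root"])


class TestLikelihood:
    def test_matches_enumeration_oracle(self, tree3):
        """Pruning equals the exhaustive ancestral-state sum on 3 species."""
        n_max = 6
        prior = np.zeros(n_max + 1)
        prior[1:] = 1.0 / n_max
        for counts in [{"A": 1, "B": 1, "C": 1}, {"A": 2, "B": 1, "C": 0}, {"A": 2, "B": 2, "C": 1}]:
            profile = FamilyProfile("f", counts)
            model = GainLossModel(lam=0.004, tree=tree3, n_max=n_max)
            got = family_loglik(profile, model)
            want = oracle_family_likelihood(profile, tree3, 0.004, n_max, prior)
            assert got == pytest.approx(np.log(want), abs=1e-9)

    def test_likelihood_tends_to_one_for_tiny_lambda(self, tree3):
        profile = FamilyProfile("f", {"A": 1, "B": 1, "C": 1})
        point_prior = np.zeros(11)
        point_prior[1] = 1.0
        model = GainLossModel(lam=1e-9, tree=tree3, n_max=10, root_prior=point_prior)
        assert family_loglik(profile, model) == pytest.approx(0.0, abs=1e-5)

    def test_truncation_stability(self, tree3):
        profile = FamilyProfile("f", {"A": 3, "B": 2, "C": 4})
        lls = []
        for n_max in (16, 32, 48):
            model = GainLossModel(lam=0.004, tree=tree3, n_max=n_max)
            # same effective root prior support for comparability
            prior = np.zeros(n_max + 1)
            prior[1:17] = 1.0 / 16
            model.root_prior = prior
            lls.append(family_loglik(profile, model))
        assert lls[0] == pytest.approx(lls[2], abs=1e-8)
        assert lls[1] == pytest.approx(lls[2], abs=1e-8)

    def test_n_max_below_observed_errors(self, tree3):
        profile = FamilyProfile("f", {"A": 9, "B": 1, "C": 1})
        model = GainLossModel(lam=0.004, tree=tree3, n_max=5)
        with pytest.raises(ValueError, match="n_max"):
            family_loglik(profile, model)


class TestRootPresence:
    def test_spanning_profile_kept(self, tree3):
        kept = root_presence_filter(
            [FamilyProfile("f", {"A": 1, "C": 2})], tree3
        )
        assert len(kept) == 1

    def test_one_sided_profile_dropped(self, tree3):
        kept = root_presence_filter(
            [FamilyProfile("f", {"A": 1, "B": 3})], tree3
        )
        assert kept == []

    def test_matches_bruteforce_lca(self, species6, config, rng):
        profiles, _ = simulate_profiles(species6, config, n_families=60, rng=rng)
        kept = {p.family_id for p in root_presence_filter(profiles, species6)}
        left = {l.label for l in species6.root.children[0].leaves()}
        for p in profiles:
            present = p.present_species()
            spans = bool(present & left) and bool(present - left)
            assert (p.family_id in kept) == spans


class TestEstimateLambda:
    def test_recovery_at_moderate_scale(self, species6):
        config = SimulationConfig(seed=11, lambda_true=0.002)
        profiles, _ = simulate_profiles(species6, config, n_families=300)
        kept = root_presence_filter(profiles, species6)
        lam, excluded, _model, _ll = estimate_lambda(kept, species6)
        assert lam == pytest.approx(0.002, rel=0.25)

    def test_planted_outlier_excluded_first(self, species6):
        config = SimulationConfig(seed=13, lambda_true=0.0005, max_root_count=2)
        profiles, _ = simulate_profiles(species6, config, n_families=40)
        kept = root_presence_filter(profiles, species6)
        counts = {sp: 1 for sp in species6.taxa()}
        outlier_counts = dict(counts)
        outlier_counts["human"] = 60
        outlier_counts["opossum"] = 1
        kept.append(FamilyProfile("outlier", outlier_counts))
        lam, _exc, model, ll = estimate_lambda(kept, species6, n_max=70)
        worst = kept[int(np.argmin(ll))].family_id
        assert worst == "outlier"

    def test_final_scores_cover_all_profiles(self, species6):
        config = SimulationConfig(seed=17, lambda_true=0.002)
        profiles, _ = simulate_profiles(species6, config, n_families=50)
        kept = root_presence_filter(profiles, species6)
        lam, _exc, _model, ll = estimate_lambda(kept, species6)
        assert len(ll) == len(kept)
        assert np.all(np.isfinite(ll))


class TestExpansions:
    def test_constant_counts_unchanged(self, tree3):
        profile = FamilyProfile("f", {"A": 2, "B": 2, "C": 2})
        model = GainLossModel(lam=0.002, tree=tree3, n_max=10)
        _counts, labels = expansions_contractions(profile, model)
        assert set(labels.values()) == {"unchanged"}

    def test_single_low_leaf_contracted(self, tree3):
        profile = FamilyProfile("f", {"A": 4, "B": 4, "C": 1})
        model = GainLossModel(lam=0.004, tree=tree3, n_max=16)
        counts, labels = expansions_contractions(profile, model)
        assert labels["C"] == "contracted"
        assert counts["AB"] == 4

    def test_summary_equals_recount(self, species6, config):
        profiles, _ = simulate_profiles(species6, config, n_families=30)
        model = GainLossModel(lam=0.002, tree=species6, n_max=40)
        summary = gain_loss_summary(profiles, model).set_index("branch")
        tally = {}
        for p in profiles:
            _c, labels = expansions_contractions(p, model)
            for b, l in labels.items():
                tally.setdefault(b, {"expanded": 0, "contracted": 0, "unchanged": 0})
                tally[b][l] += 1
        for b, rec in tally.items():
            for k, v in rec.items():
                assert summary.loc[b, k] == v
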