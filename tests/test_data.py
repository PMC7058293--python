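"""Data model, CSV readers, effect reconstruction and curation summaries."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bnmeta
from bnmeta.data import (
    KMSummary,
    NetworkConnectivityError,
    OutcomeDataset,
    RelativeEffect,
    StudyMeta,
    Treatment,
    build_network,
    effect_from_ci,
    effect_from_km,
    effect_from_pvalue_events,
    parse_agents,
    read_arm_table,
    read_contrast_table,
    summarize_trials,
)
from bnmeta.simulate import simulate_km_tables

from conftest import make_dataset


class TestEffectFromCI:
    @pytest.mark.parametrize(
        "point, lo, hi, est, se",
        [
            (0.69, 0.55, 0.87, -0.3711, 0.1170),
            (0.68, 0.50, 0.93, -0.3857, 0.1583),
            (0.5, 0.25, 1.0, -0.6931, 0.3537),
        ],
    )
    def test_hand_values(self, point, lo, hi, est, se):
        got_est, got_se = effect_from_ci(point, lo, hi)
        assert got_est == pytest.approx(est, abs=5e-5)
        assert got_se == pytest.approx(se, abs=5e-5)

    @pytest.mark.parametrize(
        "args",
        [
            (1.0, 1.0, 1.0),  # degenerate interval
            (0.5, 0.6, 0.9),  # point below lower bound
            (0.5, 0.9, 0.6),  # reversed bounds
            (-0.5, 0.2, 0.9),  # negative ratio
        ],
    )
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            effect_from_ci(*args)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            effect_from_ci(0.5, 0.4, 0.6, level=1.5)

    @settings(derandomize=True, max_examples=60)
    @given(
        log_point=st.floats(-2, 2),
        half_width=st.floats(0.05, 2),
        level=st.floats(0.5, 0.99),
    )
    def test_round_trip(self, log_point, half_width, level):
        """Exponentiating (estimate, SE) back to a CI recovers the inputs."""
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2)
        point = math.exp(log_point)
        lo, hi = math.exp(log_point - half_width), math.exp(log_point + half_width)
        est, se = effect_from_ci(point, lo, hi, level=level)
        assert math.exp(est) == pytest.approx(point, abs=1e-6)
        assert math.exp(est - z * se) == pytest.approx(lo, abs=1e-6)
        assert math.exp(est + z * se) == pytest.approx(hi, abs=1e-6)


class TestEffectFromPvalue:
    @pytest.mark.parametrize(
        "p, e, n1, n2, est, se",
        [
            (0.05, 100, 200, 200, -0.3920, 0.2000),
            (1.0, 100, 200, 200, 0.0, 0.2000),
            (0.05, 100, 300, 100, -0.4527, 0.2309),
        ],
    )
    def test_hand_values(self, p, e, n1, n2, est, se):
        got_est, got_se = effect_from_pvalue_events(p, e, n1, n2)
        assert got_est == pytest.approx(est, abs=1e-4)
        assert got_se == pytest.approx(se, abs=1e-4)

    @settings(derandomize=True, max_examples=40)
    @given(
        p=st.floats(1e-6, 1.0),
        e=st.integers(1, 2000),
        n1=st.integers(1, 2000),
        n2=st.integers(1, 2000),
    )
    def test_sign_antisymmetry_and_se(self, p, e, n1, n2):
        """SE depends only on (events, n1, n2); flipping the favoured arm
        flips the sign of the estimate."""
        est_f, se_f = effect_from_pvalue_events(p, e, n1, n2, favours_treatment=True)
        est_a, se_a = effect_from_pvalue_events(p, e, n1, n2, favours_treatment=False)
        assert se_f == se_a == pytest.approx(1 / math.sqrt(e * n1 * n2 / (n1 + n2) ** 2))
        assert est_f == pytest.approx(-est_a)

    def test_invalid(self):
        with pytest.raises(ValueError):
            effect_from_pvalue_events(0.0, 100, 200, 200)
        with pytest.raises(ValueError):
            effect_from_pvalue_events(0.5, 0, 200, 200)


class TestEffectFromKM:
    def test_single_point_hand_value(self):
        c = KMSummary("c", (6.0,), (0.8,), n_enrolled=1000)
        t = KMSummary("t", (6.0,), (0.9,), n_enrolled=1000)
        est, se = effect_from_km(c, t)
        assert est == pytest.approx(math.log(math.log(0.9) / math.log(0.8)), abs=1e-9)
        # variance rule: 1/e_c + 1/e_t with e = n * (1 - S)
        assert se == pytest.approx(math.sqrt(1 / 200 + 1 / 100), abs=1e-9)

    def test_identical_curves_give_zero(self):
        s = tuple(np.exp(-0.05 * np.arange(1, 13)))
        c = KMSummary("c", tuple(range(1, 13)), s, n_enrolled=500)
        t = KMSummary("t", tuple(range(1, 13)), s, n_enrolled=500)
        est, _ = effect_from_km(c, t)
        assert est == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("hr", [0.5, 1.0, 2.0])
    def test_recovers_proportional_hazards(self, hr):
        """Mean log-HR error below 0.05 on simulated curves with >= 500 events."""
        errs = []
        for seed in range(5):
            c, t, truth = simulate_km_tables(hr=hr, n_per_arm=2000, seed=seed)
            est, se = effect_from_km(c, t)
            errs.append(est - truth["log_hr"])
            assert abs(est - truth["log_hr"]) < 2.5 * se + 0.05
        assert abs(np.mean(errs)) < 0.05

    def test_grid_coarsening_is_stable(self):
        c1, t1, _ = simulate_km_tables(hr=0.5, grid_step=1.0, n_per_arm=2000, seed=3)
        c3, t3, _ = simulate_km_tables(hr=0.5, grid_step=3.0, n_per_arm=2000, seed=3)
        e1, s1 = effect_from_km(c1, t1)
        e3, _ = effect_from_km(c3, t3)
        assert abs(e1 - e3) < s1

    def test_mismatched_grids_rejected(self):
        c = KMSummary("c", (1.0, 2.0), (0.9, 0.8), n_enrolled=100)
        t = KMSummary("t", (1.0, 3.0), (0.9, 0.8), n_enrolled=100)
        with pytest.raises(ValueError):
            effect_from_km(c, t)

    def test_increasing_survival_rejected(self):
        with pytest.raises(ValueError):
            KMSummary("c", (1.0, 2.0), (0.8, 0.9), n_enrolled=100)


class TestReaders:
    def test_contrast_table_natural_scale(self):
        csv = io.StringIO(
            "study,treatment,reference,measure,estimate,ci_lower,ci_upper\n"
            "SHARP,Sor,Pla,hr,0.69,0.55,0.87\n"
            "AsiaPacific,Sor,Pla,hr,0.68,0.50,0.93\n"
        )
        ds = read_contrast_table(csv)
        assert len(ds.contrasts) == 2
        assert ds.contrasts[0].estimate == pytest.approx(-0.3711, abs=5e-5)
        assert ds.contrasts[1].estimate == pytest.approx(-0.3857, abs=5e-5)

    def test_contrast_table_log_passthrough(self):
        csv = io.StringIO(
            "study,treatment,reference,measure,log_estimate,std_err\n"
            "s1,B,A,hr,0.0,0.1\ns2,B,A,hr,0.3,0.2\n"
        )
        ds = read_contrast_table(csv)
        assert ds.contrasts[0].estimate == 0.0
        assert ds.contrasts[0].std_err == 0.1

    @pytest.mark.parametrize(
        "body",
        [
            "study,treatment,reference,measure,estimate,ci_lower,ci_upper\ns,B,A,hr,0.7,0.9,0.6\n",
            "study,treatment,measure,estimate,ci_lower,ci_upper\ns,B,hr,0.7,0.6,0.9\n",
            "study,treatment,reference,measure,log_estimate,std_err\ns,B,A,hr,0.1,0.2\ns,B,A,hr,0.3,0.2\n",
            "study,treatment,reference,measure,estimate,ci_lower,ci_upper\ns,B,A,hr,-0.7,0.6,0.9\n",
            "study,treatment,reference,measure\ns,B,A,hr\n",
        ],
        ids=["reversed-ci", "missing-column", "duplicate-row", "negative-hr", "no-effect"],
    )
    def test_contrast_table_rejects_malformed(self, body):
        with pytest.raises(ValueError):
            read_contrast_table(io.StringIO(body))

    def test_arm_table(self):
        arms = read_arm_table(
            io.StringIO("study,treatment,events,total\ns1,T,10,100\ns1,C,5,100\n")
        )
        assert len(arms) == 2 and arms[0].events == 10

    def test_arm_table_all_events_boundary(self):
        arms = read_arm_table(
            io.StringIO("study,treatment,events,total\ns1,T,100,100\ns1,C,5,100\n")
        )
        assert arms[0].events == arms[0].total

    @pytest.mark.parametrize(
        "body",
        [
            "study,treatment,events,total\ns1,T,10,0\ns1,C,5,100\n",
            "study,treatment,events,total\ns1,T,101,100\ns1,C,5,100\n",
            "study,treatment,events,total\ns1,T,10,100\n",
        ],
        ids=["zero-total", "events-exceed-total", "single-arm-study"],
    )
    def test_arm_table_rejects_malformed(self, body):
        with pytest.raises(ValueError):
            read_arm_table(io.StringIO(body))


class TestTypes:
    def test_relative_effect_validation(self):
        with pytest.raises(ValueError):
            RelativeEffect("s", "A", "A", "log-hazard-ratio", 0.1, 0.1)
        with pytest.raises(ValueError):
            RelativeEffect("s", "B", "A", "log-hazard-ratio", 0.1, 0.0)

    def test_study_meta_validation(self):
        with pytest.raises(ValueError):
            StudyMeta("s", 2020, (("A", 10, 60.0),))
        with pytest.raises(ValueError):
            StudyMeta("s", 2020, (("A", 10, 60.0), ("A", 12, 61.0)))

    def test_dataset_rejects_mixed_study_rows(self):
        from bnmeta.data import BinaryArm, LOG_OR

        with pytest.raises(ValueError):
            OutcomeDataset(
                measure=LOG_OR,
                treatments=[Treatment("A"), Treatment("B")],
                contrasts=[RelativeEffect("s1", "B", "A", LOG_OR, 0.1, 0.1)],
                binary_arms=[BinaryArm("s1", "A", 5, 50), BinaryArm("s1", "B", 9, 50)],
            )

    @pytest.mark.parametrize(
        "code, agents",
        [
            ("Pla", set()),
            ("Sor", {"Sor"}),
            ("Bev + Erl", {"Bev", "Erl"}),
            ("Van 100mg", {"Van"}),
            ("Van 300mg", {"Van"}),
            ("Tig 2mg + Sor", {"Tig", "Sor"}),
        ],
    )
    def test_parse_agents(self, code, agents):
        assert set(parse_agents(code)) == agents


class TestNetwork:
    def test_single_study(self):
        net = build_network(make_dataset([("s", "B", "A", 0.1, 0.1)]))
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.edges[("A", "B")] == ("s",)

    def test_hub_removal_disconnects(self):
        ds = make_dataset(
            [
                ("s1", "Sor", "Pla", -0.3, 0.1),
                ("s2", "A", "Sor", -0.1, 0.1),
                ("s3", "B", "Pla", 0.1, 0.1),
            ]
        )
        assert build_network(ds).connected
        broken = make_dataset([("s2", "A", "Sor", -0.1, 0.1), ("s3", "B", "Pla", 0.1, 0.1)])
        with pytest.raises(NetworkConnectivityError) as err:
            build_network(broken)
        assert len(err.value.components) == 2

    def test_connectivity_matches_union_find(self):
        """Brute-force union-find oracle on random graphs of <= 12 nodes."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(3, 13)
            nodes = [f"T{i}" for i in range(n)]
            m = rng.integers(2, n + 3)
            rows = []
            for j in range(m):
                a, b = rng.choice(n, size=2, replace=False)
                rows.append((f"s{j}", nodes[a], nodes[b], 0.0, 0.1))
            # union-find over the same edges, restricted to referenced nodes
            parent = {}

            def find(x):
                parent.setdefault(x, x)
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for _, a, b, _, _ in rows:
                parent[find(a)] = find(b)
            connected = len({find(x) for x in parent}) == 1
            ds = make_dataset(rows)
            if connected:
                assert build_network(ds).connected
            else:
                with pytest.raises(NetworkConnectivityError):
                    build_network(ds)


class TestCuration:
    def test_bundled_table_summary(self):
        s = summarize_trials(bnmeta.load_hcc_trial_table())
        assert s.n_studies == 22
        assert s.total_patients == 9288
        assert (s.min_trial_size, s.max_trial_size) == (67, 1155)
        assert (s.min_median_age, s.max_median_age) == (51.0, 70.0)
        assert s.n_distinct_agents == 13

    def test_totals_match_brute_force(self):
        """Summary totals equal direct sums over the raw fixture rows."""
        import pandas as pd
        from importlib import resources

        path = resources.files("bnmeta.datasets").joinpath("hcc_trials.csv")
        with resources.as_file(path) as p:
            raw = pd.read_csv(p)
        s = summarize_trials(bnmeta.load_hcc_trial_table())
        assert s.total_patients == raw["n"].sum()
        assert s.n_studies == raw["study"].nunique()
        sizes = raw.groupby("study")["n"].sum()
        assert (s.min_trial_size, s.max_trial_size) == (sizes.min(), sizes.max())
        ages = raw["median_age"].dropna()
        assert (s.min_median_age, s.max_median_age) == (ages.min(), ages.max())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_trials([])
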