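import numpy as np
import pandas as pd
import pytest

from cfnet import phospho
from cfnet.types import KinaseSubstrateMap, PhosphoSiteProfile
from oracles import hypergeom_uppertail


def raw_table(rows):
    records = []
    for protein, pos, res, rev, con, intensities in rows:
        rec = {
            "protein": protein,
            "position": pos,
            "residue": res,
            "localization_prob": 0.95,
            "delta_score": 40.0,
            "reverse": rev,
            "contaminant": con,
        }
        for j, v in enumerate(intensities, start=1):
            rec[f"intensity_{j}"] = v
        records.append(rec)
    return pd.DataFrame.from_records(records)


def site(protein, pos, res, intensities, exp="e1"):
    return PhosphoSiteProfile(
        protein=protein, position=pos, residue=res,
        intensities=np.asarray(intensities, dtype=float), experiment_id=exp,
    )


class TestFilterSites:
    def test_reverse_and_contaminant_removed(self):
        raw = raw_table(
            [
                ("P1", 21, "S", False, False, [1.0, 2.0]),
                ("REV__P2", 5, "Y", True, False, [1.0, 2.0]),
                ("CON__P3", 9, "T", False, True, [1.0, 2.0]),
            ]
        )
        sites = phospho.filter_sites(raw, experiment_id="e1")
        assert [s.protein for s in sites] == ["P1"]

    def test_clean_table_is_identity(self):
        raw = raw_table([("P1", 1, "S", False, False, [1.0]), ("P2", 2, "T", False, False, [2.0])])
        assert len(phospho.filter_sites(raw)) == 2

    def test_all_flagged_gives_empty_list_not_error(self):
        raw = raw_table([("REV__P", 1, "S", True, False, [1.0])])
        assert phospho.filter_sites(raw) == []


class TestDetectionCounts:
    def test_single_experiment_fraction_count(self):
        s = site("P1", 10, "S", [1.0, np.nan, np.nan, np.nan, 2.0, np.nan, np.nan, np.nan, 3.0])
        counts = phospho.detection_counts([s])
        assert counts.iloc[0]["n_fractions"] == 3
        assert counts.iloc[0]["n_experiments"] == 1

    def test_same_site_across_two_experiments(self):
        s1 = site("P1", 10, "S", [1.0, 2.0, np.nan], exp="e1")
        s2 = site("P1", 10, "S", [np.nan, 1.0, 2.0, 3.0], exp="e2")
        counts = phospho.detection_counts([s1, s2])
        assert counts.iloc[0]["n_fractions"] == 5
        assert counts.iloc[0]["n_experiments"] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        sites = []
        for i in range(20):
            intens = rng.uniform(1, 10, 8)
            intens[rng.random(8) < 0.5] = np.nan
            sites.append(
                site(f"P{i % 5}", int(rng.integers(1, 4)) * 7, "STY"[i % 3], intens,
                     exp=f"e{i % 3}")
            )
        counts = phospho.detection_counts(sites)
        for row in counts.itertuples(index=False):
            key = (row.protein, row.position, row.residue)
            expected = sum(
                int(np.sum(~np.isnan(s.intensities))) for s in sites if s.site_key == key
            )
            assert row.n_fractions == expected


class TestPrioritize:
    def test_boundary_inclusive_at_five(self):
        counts = pd.DataFrame(
            {
                "protein": ["A", "B", "C"],
                "position": [1, 2, 3],
                "residue": ["S", "T", "Y"],
                "n_fractions": [6, 3, 5],
                "n_experiments": [1, 1, 1],
            }
        )
        out = phospho.prioritize(counts)
        assert list(out["protein"]) == ["A", "C"]

    def test_threshold_one_keeps_all_detected(self):
        counts = pd.DataFrame(
            {"protein": ["A"], "position": [1], "residue": ["S"],
             "n_fractions": [1], "n_experiments": [1]}
        )
        assert len(phospho.prioritize(counts, min_fractions=1)) == 1

    def test_idempotent_pure_filter(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(30)],
                "position": range(30),
                "residue": ["S"] * 30,
                "n_fractions": rng.integers(0, 12, 30),
                "n_experiments": 1,
            }
        )
        once = phospho.prioritize(counts)
        twice = phospho.prioritize(once)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once.index) == set(range(len(once)))


class TestResidueProportions:
    def test_worked_example(self):
        sites = [
            site("P1", 1, "S", [1.0]),
            site("P2", 2, "S", [1.0]),
            site("P3", 3, "T", [1.0]),
            site("P4", 4, "Y", [1.0]),
        ]
        props = phospho.residue_proportions(sites)
        assert props == {"S": 0.5, "T": 0.25, "Y": 0.25}

    def test_duplicate_sites_counted_once(self):
        sites = [site("P1", 1, "S", [1.0], exp="e1"), site("P1", 1, "S", [1.0], exp="e2")]
        assert phospho.residue_proportions(sites)["S"] == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            phospho.residue_proportions([])

    def test_proportions_sum_to_one_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        sites = [
            site(f"P{i}", int(rng.integers(1, 100)), "STY"[int(rng.integers(0, 3))], [1.0])
            for i in range(50)
        ]
        assert sum(phospho.residue_proportions(sites).values()) == pytest.approx(1.0)


class TestKsea:
    def test_matches_closed_form(self):
        background = {(f"P{i}", 1, "S") for i in range(100)}
        foreground = {(f"P{i}", 1, "S") for i in range(10)}
        substrates = {(f"P{i}", 1, "S") for i in range(5)} | {
            (f"P{i}", 1, "S") for i in range(50, 65)
        }  # 5 in foreground, 20 total in background
        kmap = KinaseSubstrateMap(substrates={"K1": frozenset(substrates)})
        result = phospho.ksea_hypergeometric(foreground, background, kmap)
        expected = hypergeom_uppertail(5, 100, 20, 10)
        assert result.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-10)
        assert result.iloc[0]["overlap"] == 5

    def test_kinase_without_background_substrates_skipped(self):
        background = {("P1", 1, "S"), ("P2", 2, "T")}
        kmap = KinaseSubstrateMap(substrates={"K1": frozenset({("Z", 9, "Y")})})
        result = phospho.ksea_hypergeometric(background, background, kmap)
        assert len(result) == 0

    def test_foreground_equal_background_gives_p_one(self):
        background = {(f"P{i}", 1, "S") for i in range(20)}
        kmap = KinaseSubstrateMap(
            substrates={"K1": frozenset({(f"P{i}", 1, "S") for i in range(4)})}
        )
        result = phospho.ksea_hypergeometric(background, background, kmap)
        assert result.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_foreground_not_subset_is_error(self):
        with pytest.raises(ValueError):
            phospho.ksea_hypergeometric({("A", 1, "S")}, {("B", 1, "S")},
                                        KinaseSubstrateMap(substrates={"K": frozenset({("A", 1, "S")})}))

    def test_bh_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(2)
        background = {(f"P{i}", 1, "S") for i in range(200)}
        foreground = {(f"P{i}", 1, "S") for i in range(40)}
        substrates = {}
        for k in range(8):
            members = rng.choice(200, size=int(rng.integers(5, 40)), replace=False)
            substrates[f"K{k}"] = frozenset((f"P{i}", 1, "S") for i in members)
        result = phospho.ksea_hypergeometric(foreground, background,
                                             KinaseSubstrateMap(substrates=substrates))
        df = result.sort_values("p_value")
        assert np.all(np.diff(df["q_value"]) >= -1e-12)
        assert np.all((df["p_value"] > 0) & (df["p_value"] <= 1))


class TestStoichiometryProfile:
    def test_ratio_is_elementwise_division(self):
        parent = np.array([10.0, 20.0, np.nan, 40.0])
        s = site("P1", 1, "S", [1.0, np.nan, 3.0, 8.0])
        ratios, flag = phospho.stoichiometry_profile(s, parent)
        np.testing.assert_allclose(ratios[[0, 3]], [0.1, 0.2])
        assert np.isnan(ratios[1]) and np.isnan(ratios[2])

    def test_two_peak_parent_assigns_nearest_peak(self):
        f = np.arange(40, dtype=float)
        parent = 100 * np.exp(-0.5 * ((f - 12) / 2) ** 2) + 80 * np.exp(-0.5 * ((f - 30) / 2) ** 2)
        site_intens = np.full(40, np.nan)
        site_intens[11:14] = [5.0, 9.0, 4.0]  # max at fraction index 12
        s = site("P1", 21, "S", site_intens)
        _, flag = phospho.stoichiometry_profile(s, parent)
        assert flag == 1
        site2 = np.full(40, np.nan)
        site2[29:32] = [4.0, 9.0, 3.0]
        _, flag2 = phospho.stoichiometry_profile(site("P1", 22, "S", site2), parent)
        assert flag2 == 2

    def test_single_peak_parent_always_flag_one(self):
        f = np.arange(30, dtype=float)
        parent = 50 * np.exp(-0.5 * ((f - 15) / 3) ** 2)
        site_intens = np.full(30, np.nan)
        site_intens[10] = 2.0
        _, flag = phospho.stoichiometry_profile(site("P1", 3, "T", site_intens), parent)
        assert flag == 1

    def test_no_overlap_gives_undefined_flag(self):
        parent = np.array([np.nan, np.nan, 10.0, 20.0])
        s = site("P1", 1, "S", [1.0, 2.0, np.nan, np.nan])
        ratios, flag = phospho.stoichiometry_profile(s, parent)
        assert flag is None
        assert np.isnan(ratios).all()
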