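"""Touch classification, conditioned profiles, random-split null, dwell."""

import numpy as np
import pandas as pd
import pytest

from ahyflex import (
    AnnotatedDuplex,
    ContactModel,
    EnsembleConfig,
    Modification,
    classify_frames,
    conditioned_profiles,
    contact_dwell_statistics,
    contacts_from_distances,
    generate_ensemble,
    interaction_frequencies,
    partition_counts,
    random_split_control,
)
from ahyflex.contacts import ContactError
from ahyflex.structure import ParameterTrajectory


def distance_table(distances_by_site: dict[int, list[float]]) -> pd.DataFrame:
    rows = []
    for site, values in distances_by_site.items():
        for f, d in enumerate(values, start=1):
            rows.append({"frame": f, "site": site, "distance": d})
    return pd.DataFrame(rows)


def planted_shift_ensemble(n_frames: int, seed: int, roll_shift: float = 4.0):
    """Single-site azide ensemble with a planted roll shift while touching."""
    duplex = AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                             [Modification(8, "top", "ahy")], name="ahyCx1(8)")
    config = EnsembleConfig(
        duplex, n_frames=n_frames, n_replicas=1, seed=seed,
        contact_model=ContactModel(p_touch=0.5, mean_dwell_frames=5.0,
                                   touch_roll_shift=roll_shift,
                                   touch_twist_shift=0.0, touch_slide_shift=0.0))
    return generate_ensemble(config)


class TestClassification:
    def test_strict_less_than_boundary(self):
        table = contacts_from_distances(
            distance_table({8: [4.4, 4.5, 4.6]}), threshold=4.5)
        assert list(table.records["touching"]) == [True, False, False]
        assert list(table.any_touch()) == [True, False, False]

    def test_any_touch_is_or_over_sites(self):
        table = contacts_from_distances(
            distance_table({8: [4.4, 5.0], 16: [6.0, 4.6]}), threshold=4.5)
        assert list(table.any_touch()) == [True, False]

    def test_threshold_must_be_positive(self):
        with pytest.raises(ContactError):
            contacts_from_distances(distance_table({8: [1.0]}), threshold=0.0)

    def test_coordinate_classification_matches_latent_truth(self):
        frags = EnsembleConfig(
            AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                            [Modification(8, "top", "ahy"), Modification(16, "top", "ahy")],
                            name="ahyCx2"),
            n_frames=12, n_replicas=1, seed=31, contact_model=ContactModel(p_touch=0.6))
        ens = generate_ensemble(frags, mode="coordinates")
        table = classify_frames(ens.models[0], threshold=4.5)
        latent = ens.latent[ens.latent.replica == 0]
        merged = table.records.merge(latent, on=["frame", "site"], suffixes=("", "_truth"))
        assert (merged["touching"] == merged["touching_truth"]).all()

    def test_site_without_azide_rejected(self, duplex_c):
        from ahyflex.structure import ideal_bdna_parameters, rebuild_duplex, DuplexTrajectory

        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        traj = DuplexTrajectory.from_models([model])
        with pytest.raises(ContactError):
            classify_frames(traj)


class TestPartition:
    def test_counts_always_sum_to_total(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            table = contacts_from_distances(
                distance_table({8: rng.uniform(2, 9, 50).tolist(),
                                16: rng.uniform(2, 9, 50).tolist()}))
            n_any, n_no, n_total = partition_counts(table)
            assert n_any + n_no == n_total == 50

    def test_generator_counts_match_latent_truth_exactly(self):
        ens = planted_shift_ensemble(2000, seed=6)
        table = contacts_from_distances(ens.latent[ens.latent.replica == 0])
        n_any, n_no, n_total = partition_counts(table)
        assert n_total == 2000
        assert n_any == int(ens.any_touch(0).sum())

    def test_all_touch_partition(self):
        table = contacts_from_distances(distance_table({8: [3.0] * 7}))
        assert partition_counts(table) == (7, 0, 7)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        table_raw = distance_table({8: rng.uniform(2, 9, 400).tolist()})
        counts = [partition_counts(contacts_from_distances(table_raw, t))[0]
                  for t in (3.0, 4.5, 6.0)]
        assert counts[0] <= counts[1] <= counts[2]


class TestConditionedProfiles:
    def test_planted_roll_shift_recovered_at_site_steps(self):
        ens = planted_shift_ensemble(10_000, seed=9)
        traj = ens.trajectories[0]
        summary = conditioned_profiles(traj, ens.any_touch(0), ("roll",))
        touch = summary.mean_profile("any touch", "roll")
        free = summary.mean_profile("no touch", "roll")
        n_t = summary.group_sizes["any touch"]
        n_f = summary.group_sizes["no touch"]
        sd_t = summary.sd_profile("any touch", "roll")
        sd_f = summary.sd_profile("no touch", "roll")
        se = np.sqrt(sd_t**2 / n_t + sd_f**2 / n_f)
        diff = touch - free
        site_steps = np.array([7, 8, 9]) - 1
        far_steps = np.array([3, 13, 20]) - 1
        assert np.all(np.abs(diff[site_steps] - 4.0) < 3 * se[site_steps])
        assert np.all(np.abs(diff[far_steps]) < 3 * se[far_steps])

    def test_mixture_broadening_in_any_touch_group(self, duplex_ahycx4):
        """With several independently touching sites, the any-touch group is a
        mixture at each site, so its SD exceeds the pure no-touch SD there."""
        config = EnsembleConfig(duplex_ahycx4, n_frames=10_000, n_replicas=1, seed=12,
                                contact_model=ContactModel(p_touch=0.4,
                                                           touch_roll_shift=6.0))
        ens = generate_ensemble(config)
        summary = conditioned_profiles(ens.trajectories[0], ens.any_touch(0), ("roll",))
        sd_t = summary.sd_profile("any touch", "roll")
        sd_f = summary.sd_profile("no touch", "roll")
        site_steps = np.array([7, 8, 9, 15, 16, 17]) - 1
        assert np.all(sd_t[site_steps] >= sd_f[site_steps])

    def test_degenerate_single_frame_group_flagged(self):
        rng = np.random.default_rng(2)
        traj = ParameterTrajectory(rng.normal(size=(5, 4, 6)), rng.normal(size=(5, 5, 6)))
        flags = np.array([True, False, False, False, False])
        summary = conditioned_profiles(traj, flags, ("roll",))
        assert summary.group_sizes == {"any touch": 1, "no touch": 4}
        assert np.isnan(summary.sd_profile("any touch", "roll")).all()
        assert np.isfinite(summary.sd_profile("no touch", "roll")).all()

    def test_empty_group_instructs_user(self):
        rng = np.random.default_rng(3)
        traj = ParameterTrajectory(rng.normal(size=(4, 3, 6)), rng.normal(size=(4, 4, 6)))
        with pytest.raises(ContactError, match="threshold or more frames"):
            conditioned_profiles(traj, np.ones(4, dtype=bool), ("roll",))

    def test_flag_length_mismatch(self):
        rng = np.random.default_rng(4)
        traj = ParameterTrajectory(rng.normal(size=(4, 3, 6)), rng.normal(size=(4, 4, 6)))
        with pytest.raises(ContactError, match="length"):
            conditioned_profiles(traj, np.zeros(5, dtype=bool), ("roll",))


class TestRandomSplitControl:
    def test_exact_sizes_and_determinism(self):
        rng = np.random.default_rng(5)
        traj = ParameterTrajectory(rng.normal(size=(9001, 4, 6)),
                                   rng.normal(size=(9001, 5, 6)))
        a = random_split_control(traj, (355, 8646), seed=1, parameters=("roll",))
        b = random_split_control(traj, (355, 8646), seed=1, parameters=("roll",))
        assert a.group_sizes == {"split A": 355, "split B": 8646}
        assert a.table.equals(b.table)

    def test_size_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        traj = ParameterTrajectory(rng.normal(size=(10, 3, 6)), rng.normal(size=(10, 4, 6)))
        with pytest.raises(ContactError, match="sum"):
            random_split_control(traj, (3, 4), seed=0)

    def test_no_planted_difference_survives_random_split(self):
        """A random split of a shift-carrying ensemble shows no step with a
        mean difference beyond chance (checked with a fixed seed)."""
        ens = planted_shift_ensemble(10_000, seed=13)
        traj = ens.trajectories[0]
        n_any = int(ens.any_touch(0).sum())
        summary = random_split_control(traj, (n_any, traj.n_frames - n_any),
                                       seed=99, parameters=("roll",))
        diff = (summary.mean_profile("split A", "roll")
                - summary.mean_profile("split B", "roll"))
        sd_a = summary.sd_profile("split A", "roll")
        sd_b = summary.sd_profile("split B", "roll")
        se = np.sqrt(sd_a**2 / n_any + sd_b**2 / (traj.n_frames - n_any))
        # 24 steps at the 3-SE level: apply a 4-SE family bound
        assert np.all(np.abs(diff) < 4 * se)


class TestInteractionFrequencies:
    def test_no_touch_gives_empty_graph(self):
        duplex = AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                                 [Modification(8, "top", "ahy")], name="x")
        config = EnsembleConfig(duplex, n_frames=6, n_replicas=1, seed=2,
                                contact_model=ContactModel(p_touch=0.0))
        ens = generate_ensemble(config, mode="coordinates")
        graph = interaction_frequencies(ens.models[0])
        assert graph.empty

    def test_constant_touch_gives_unit_frequency_edge(self):
        duplex = AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                                 [Modification(8, "top", "ahy")], name="x")
        config = EnsembleConfig(duplex, n_frames=6, n_replicas=1, seed=3,
                                contact_model=ContactModel(p_touch=1.0))
        ens = generate_ensemble(config, mode="coordinates")
        graph = interaction_frequencies(ens.models[0])
        assert not graph.empty
        assert graph["frequency"].between(0, 1).all()
        assert (graph["frequency"] == 1.0).any()

    def test_frequencies_match_latent_touch_rate(self):
        duplex = AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                                 [Modification(8, "top", "ahy")], name="x")
        config = EnsembleConfig(duplex, n_frames=40, n_replicas=1, seed=4,
                                contact_model=ContactModel(p_touch=0.5))
        ens = generate_ensemble(config, mode="coordinates")
        graph = interaction_frequencies(ens.models[0])
        touch_rate = ens.latent["touching"].mean()
        # every frame that touches contributes at least one under-threshold
        # residue, so the summed per-residue attribution cannot fall short
        per_frame_any = graph.groupby("site")["frequency"].max().iloc[0]
        assert per_frame_any <= 1.0
        assert graph["frequency"].max() >= touch_rate - 1e-9


class TestDwell:
    def test_run_length_hand_example(self):
        stats = contact_dwell_statistics(np.array([True, True, False, True]))
        assert sorted(stats.run_lengths.tolist()) == [1, 2]
        assert stats.mean_frames == pytest.approx(1.5)

    def test_constant_true_single_run(self):
        stats = contact_dwell_statistics(np.ones(50, dtype=bool))
        assert stats.n_runs == 1
        assert stats.run_lengths.tolist() == [50]

    def test_stride_converts_to_time(self):
        stats = contact_dwell_statistics(np.array([True, True, False]), frame_stride=0.011)
        assert stats.mean_time == pytest.approx(2 * 0.011)

    def test_generator_dwell_matches_configuration(self):
        """Mean dwell within 20% of the configured value at n >= 5000."""
        duplex = AnnotatedDuplex("GCTCTCTCGAAGCAACGAGAACAGT",
                                 [Modification(8, "top", "ahy")], name="x")
        config = EnsembleConfig(duplex, n_frames=8000, n_replicas=1, seed=5,
                                contact_model=ContactModel(p_touch=0.554,
                                                           mean_dwell_frames=9.0))
        ens = generate_ensemble(config)
        site_flags = ens.latent.sort_values("frame")["touching"].to_numpy()
        stats = contact_dwell_statistics(site_flags)
        assert stats.mean_frames == pytest.approx(9.0, rel=0.20)
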