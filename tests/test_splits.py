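import numpy as np
import pytest

from ppgbp.splits import (InfeasibleQuotaError, SplitConfigurationError,
                          TailQuotas, load_split, make_aami_split,
                          make_calib_split, make_calibfree_split, save_split,
                          verify_split)

from conftest import make_label_store


def subjects_of(store, idx):
    return set(store.subject_id[idx])


class TestCalibSplit:
    def test_every_subject_in_all_four_parts(self):
        store = make_label_store(n_subjects=10, segments_per_subject=10)
        split = make_calib_split(store, 0.1, 0.1, 0.1, seed=0)
        all_subjects = set(store.subject_id)
        for part in split.parts().values():
            assert subjects_of(store, part) == all_subjects

    def test_partition_of_all_indices(self):
        store = make_label_store(n_subjects=8, segments_per_subject=6)
        split = make_calib_split(store, seed=1)
        combined = np.concatenate(list(split.parts().values()))
        assert sorted(combined.tolist()) == list(range(store.n))

    def test_determinism(self):
        store = make_label_store()
        a = make_calib_split(store, seed=7)
        b = make_calib_split(store, seed=7)
        for k in a.parts():
            np.testing.assert_array_equal(a.parts()[k], b.parts()[k])

    def test_subject_with_too_few_segments_listed(self):
        store = make_label_store(n_subjects=3, segments_per_subject=3)
        with pytest.raises(SplitConfigurationError, match="s000"):
            make_calib_split(store)


class TestCalibFreeSplit:
    def test_no_subject_overlap(self):
        store = make_label_store(n_subjects=20)
        split = make_calibfree_split(store, seed=0)
        train_side = (subjects_of(store, split.train)
                      | subjects_of(store, split.val)
                      | subjects_of(store, split.calib))
        assert not train_side & subjects_of(store, split.test)

    def test_subject_union_is_everyone(self):
        store = make_label_store(n_subjects=15)
        split = make_calibfree_split(store, seed=2)
        union = set().union(*(subjects_of(store, p)
                              for p in split.parts().values()))
        assert union == set(store.subject_id)

    def test_subject_counts_follow_benchmark_proportions(self):
        # proportions of the emulated Vital calibration-free design:
        # 1158 train / 90 val / 45 calib / 144 test subjects (of 1437)
        store = make_label_store(n_subjects=200, segments_per_subject=4)
        fr_test, fr_val, fr_calib = 144 / 1437, 90 / 1437, 45 / 1437
        split = make_calibfree_split(store, fr_test, fr_val, fr_calib, seed=3)
        counts = {k: len(subjects_of(store, v))
                  for k, v in split.parts().items()}
        assert abs(counts["test"] - 200 * fr_test) <= 1
        assert abs(counts["val"] - 200 * fr_val) <= 1
        assert abs(counts["calib"] - 200 * fr_calib) <= 1
        assert counts["train"] == 200 - counts["test"] - counts["val"] - counts["calib"]

    def test_too_few_subjects(self):
        store = make_label_store(n_subjects=3)
        with pytest.raises(SplitConfigurationError, match="subjects"):
            make_calibfree_split(store)


class TestAamiSplit:
    @staticmethod
    def tailed_store():
        rng = np.random.default_rng(0)
        a = make_label_store(n_subjects=30, segments_per_subject=4,
                             sbp_mean=125, sbp_sd=28, rng=rng)
        return a

    def test_quotas_verified_by_counting(self):
        store = self.tailed_store()
        quotas = TailQuotas(low_threshold=100, low_frac=0.05,
                            high_threshold=160, high_frac=0.05,
                            mid_threshold=140, mid_frac=0.20)
        split = make_aami_split(store, quotas=quotas, test_subject_frac=0.2,
                                seed=0)
        sbp = store.sbp[split.test]
        assert (sbp <= 100).mean() >= 0.05
        assert (sbp >= 160).mean() >= 0.05
        assert (sbp >= 140).mean() >= 0.20

    def test_subject_disjointness(self):
        store = self.tailed_store()
        split = make_aami_split(store, seed=1, test_subject_frac=0.2)
        assert not (subjects_of(store, split.train)
                    & subjects_of(store, split.test))

    def test_zero_quotas_degenerate_to_calibfree(self):
        store = self.tailed_store()
        quotas = TailQuotas(low_frac=0.0, high_frac=0.0, mid_frac=0.0)
        split = make_aami_split(store, quotas=quotas, seed=4)
        free = make_calibfree_split(store, seed=4)
        np.testing.assert_array_equal(split.test, free.test)
        assert split.scenario == "aami"

    def test_infeasible_quota_reports_achieved(self):
        store = make_label_store(n_subjects=10, sbp_mean=120, sbp_sd=2)
        quotas = TailQuotas(high_threshold=200, high_frac=0.5)
        with pytest.raises(InfeasibleQuotaError) as exc:
            make_aami_split(store, quotas=quotas, seed=0)
        assert "achieved" in str(exc.value) or exc.value.achieved is not None


class TestVerifySplit:
    def test_constructors_pass_their_own_checker(self):
        store = self.store = make_label_store(n_subjects=20,
                                              segments_per_subject=6)
        for split in (make_calib_split(store, seed=0),
                      make_calibfree_split(store, seed=0),
                      make_aami_split(store, quotas=TailQuotas(
                          low_frac=0, high_frac=0, mid_frac=0), seed=0)):
            assert all(verify_split(store, split).values())

    def test_constructed_violation_detected(self):
        store = make_label_store(n_subjects=20)
        split = make_calibfree_split(store, seed=0)
        # move one test index into train: its subject now straddles both
        split.train = np.append(split.train, split.test[0])
        split.test = split.test[1:]
        report = verify_split(store, split)
        assert report["scenario_semantics"] is False

    def test_out_of_range_raises(self):
        store = make_label_store(n_subjects=5)
        split = make_calibfree_split(store, seed=0)
        split.test = np.append(split.test, store.n + 10)
        with pytest.raises(IndexError):
            verify_split(store, split)


def test_split_json_roundtrip(tmp_path):
    store = make_label_store(n_subjects=12)
    split = make_aami_split(store, quotas=TailQuotas(low_frac=0, high_frac=0,
                                                     mid_frac=0), seed=5)
    path = tmp_path / "split.json"
    save_split(split, path)
    back = load_split(path)
    assert back.scenario == split.scenario
    assert back.quotas == split.quotas
    for k in split.parts():
        np.testing.assert_array_equal(back.parts()[k], split.parts()[k])
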