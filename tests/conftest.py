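import numpy as np
import pytest

from ppgbp.store import SegmentStore


def make_label_store(n_subjects=12, segments_per_subject=6, site="siteA",
                     sbp_mean=120.0, sbp_sd=18.0, dbp_mean=65.0, dbp_sd=10.0,
                     sig_len=16, seed=0, rng=None) -> SegmentStore:
    """Store with tiny placeholder waveforms: cheap carrier for label,
    subject and site structure (split/adaptation/evaluation tests)."""
    rng = rng or np.random.default_rng(seed)
    signals, sbp, dbp, subj, sites = [], [], [], [], []
    for j in range(n_subjects):
        s0 = np.clip(rng.normal(sbp_mean, sbp_sd), 80, 230)
        d0 = np.clip(rng.normal(dbp_mean, dbp_sd), 40, min(s0 - 20, 120))
        for _ in range(segments_per_subject):
            signals.append(rng.normal(size=sig_len))
            sbp.append(np.clip(s0 + rng.normal(0, 4), 25, 255))
            dbp.append(np.clip(d0 + rng.normal(0, 3), 21, sbp[-1] - 11))
            subj.append(f"{site}_s{j:03d}")
            sites.append(site)
    return SegmentStore(signals=np.array(signals, dtype=object),
                        sbp=np.array(sbp), dbp=np.array(dbp),
                        subject_id=np.array(subj), site_id=np.array(sites))


@pytest.fixture
def label_store() -> SegmentStore:
    return make_label_store()


@pytest.fixture
def two_site_store() -> SegmentStore:
    rng = np.random.default_rng(42)
    a = make_label_store(n_subjects=6, segments_per_subject=5, site="alpha",
                         sig_len=80, rng=rng)
    b = make_label_store(n_subjects=5, segments_per_subject=4, site="beta",
                         sbp_mean=140.0, sig_len=96, rng=rng)
    return SegmentStore(
        signals=np.concatenate([a.signals, b.signals]),
        sbp=np.concatenate([a.sbp, b.sbp]),
        dbp=np.concatenate([a.dbp, b.dbp]),
        subject_id=np.concatenate([a.subject_id, b.subject_id]),
        site_id=np.concatenate([a.site_id, b.site_id]))
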