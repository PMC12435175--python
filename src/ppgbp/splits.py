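"""Train/val/calib/test index sets realizing the three benchmark scenarios.

* **calib** -- every subject contributes segments to all four parts, so a
  model may exploit subject-specific patterns seen during training
  (subject-specific calibration via memorization).
* **calibfree** -- subjects are partitioned: all segments of a subject
  land in exactly one part, so the test set contains only unseen
  subjects.
* **aami** -- subject-disjoint like calibfree, but test subjects are
  greedily chosen so the test set emphasizes the tails of the SBP
  distribution, after the device-validation population pattern.

The calibration subset is constructed and stored for structural
fidelity but is not consumed by the training pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .store import SegmentStore

__all__ = ["DatasetSplit", "TailQuotas", "SplitConfigurationError",
           "InfeasibleQuotaError", "make_calib_split", "make_calibfree_split",
           "make_aami_split", "verify_split", "save_split", "load_split",
           "DEFAULT_FRACTIONS"]

# segment-count proportions of the benchmark's calibration-free design
# (~80% of subjects train, ~6% validation, ~3% calibration, ~10% test)
DEFAULT_FRACTIONS = {"test": 0.10, "val": 0.06, "calib": 0.03}


class SplitConfigurationError(ValueError):
    pass


class InfeasibleQuotaError(ValueError):
    def __init__(self, msg: str, achieved: dict):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class TailQuotas:
    """Minimum test-set fractions in the SBP tails (device-validation
    style).  Defaults: >=5% of test segments with SBP <= 100 mmHg,
    >=5% with SBP >= 160, >=20% with SBP >= 140."""

    low_threshold: float = 100.0
    low_frac: float = 0.05
    high_threshold: float = 160.0
    high_frac: float = 0.05
    mid_threshold: float = 140.0
    mid_frac: float = 0.20

    def fractions(self, sbp: np.ndarray) -> dict:
        n = max(len(sbp), 1)
        return {"low": float((sbp <= self.low_threshold).sum() / n),
                "high": float((sbp >= self.high_threshold).sum() / n),
                "mid": float((sbp >= self.mid_threshold).sum() / n)}

    def satisfied(self, sbp: np.ndarray) -> bool:
        f = self.fractions(sbp)
        return (f["low"] >= self.low_frac and f["high"] >= self.high_frac
                and f["mid"] >= self.mid_frac)

    @property
    def trivial(self) -> bool:
        return self.low_frac <= 0 and self.high_frac <= 0 and self.mid_frac <= 0


@dataclass
class DatasetSplit:
    scenario: str                      # calib | calibfree | aami
    train: np.ndarray
    val: np.ndarray
    calib: np.ndarray
    test: np.ndarray
    source_sites: list[str] = field(default_factory=list)
    seed: int = 0
    quotas: TailQuotas | None = None

    def parts(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "val": self.val,
                "calib": self.calib, "test": self.test}


def _subject_groups(store: SegmentStore) -> dict[str, np.ndarray]:
    order = {}
    for i, s in enumerate(store.subject_id):
        order.setdefault(s, []).append(i)
    return {s: np.asarray(v, dtype=np.intp) for s, v in order.items()}


def _part_counts(n: int, test_frac: float, val_frac: float,
                 calib_frac: float) -> tuple[int, int, int]:
    """At least one element per non-empty part where feasible."""
    n_test = max(1, int(round(test_frac * n)))
    n_val = max(1, int(round(val_frac * n)))
    n_calib = max(1, int(round(calib_frac * n)))
    while n - (n_test + n_val + n_calib) < 1:  # keep >= 1 train element
        if n_calib > 1:
            n_calib -= 1
        elif n_val > 1:
            n_val -= 1
        else:
            n_test -= 1
    return n_test, n_val, n_calib


# ----------------------------------------------------------------------
def make_calib_split(store: SegmentStore, test_frac: float = 0.10,
                     val_frac: float = 0.08, calib_frac: float = 0.02,
                     seed: int = 0) -> DatasetSplit:
    """Per-subject random partition: every subject appears in every part."""
    _check_fracs(test_frac, val_frac, calib_frac)
    groups = _subject_groups(store)
    too_few = sorted(s for s, idx in groups.items() if len(idx) < 4)
    if too_few:
        raise SplitConfigurationError(
            f"subjects with fewer than 4 segments cannot populate all four "
            f"parts: {too_few}")
    rng = np.random.default_rng(seed)
    parts = {k: [] for k in ("train", "val", "calib", "test")}
    for subject in sorted(groups):
        idx = groups[subject].copy()
        rng.shuffle(idx)
        n_test, n_val, n_calib = _part_counts(len(idx), test_frac, val_frac,
                                              calib_frac)
        parts["test"].append(idx[:n_test])
        parts["val"].append(idx[n_test:n_test + n_val])
        parts["calib"].append(idx[n_test + n_val:n_test + n_val + n_calib])
        parts["train"].append(idx[n_test + n_val + n_calib:])
    return DatasetSplit(scenario="calib",
                        **{k: np.sort(np.concatenate(v)) for k, v in parts.items()},
                        source_sites=sorted(np.unique(store.site_id).tolist()),
                        seed=seed)


def make_calibfree_split(store: SegmentStore, test_subject_frac: float = 0.10,
                         val_subject_frac: float = 0.06,
                         calib_subject_frac: float = 0.03,
                         seed: int = 0) -> DatasetSplit:
    """Random subject partition: all of a subject's segments share a part."""
    _check_fracs(test_subject_frac, val_subject_frac, calib_subject_frac)
    groups = _subject_groups(store)
    subjects = np.array(sorted(groups))
    if len(subjects) < 4:
        raise SplitConfigurationError(
            f"need at least 4 subjects for a subject-disjoint split, "
            f"have {len(subjects)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n_test, n_val, n_calib = _part_counts(len(subjects), test_subject_frac,
                                          val_subject_frac, calib_subject_frac)
    bounds = np.cumsum([n_test, n_val, n_calib])
    assign = {"test": subjects[:bounds[0]], "val": subjects[bounds[0]:bounds[1]],
              "calib": subjects[bounds[1]:bounds[2]], "train": subjects[bounds[2]:]}
    parts = {k: np.sort(np.concatenate([groups[s] for s in v]))
             for k, v in assign.items()}
    return DatasetSplit(scenario="calibfree", **parts,
                        source_sites=sorted(np.unique(store.site_id).tolist()),
                        seed=seed)


def make_aami_split(store: SegmentStore, quotas: TailQuotas = TailQuotas(),
                    test_subject_frac: float = 0.10,
                    val_subject_frac: float = 0.06,
                    calib_subject_frac: float = 0.03,
                    seed: int = 0) -> DatasetSplit:
    """Subject-disjoint split whose test set satisfies the SBP tail quotas.

    Test subjects are selected greedily in randomized order: while any
    quota is unmet, the candidate contributing the largest fraction of
    segments to the most-deficient tail is taken; otherwise the next
    random candidate.  Selection may exceed the requested test size to
    satisfy quotas; exhaustion raises with the fractions achieved.
    """
    groups = _subject_groups(store)
    subjects = np.array(sorted(groups))
    if len(subjects) < 4:
        raise SplitConfigurationError(
            f"need at least 4 subjects, have {len(subjects)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    if quotas.trivial:
        inner = make_calibfree_split(store, test_subject_frac,
                                     val_subject_frac, calib_subject_frac, seed)
        return DatasetSplit(scenario="aami", train=inner.train, val=inner.val,
                            calib=inner.calib, test=inner.test,
                            source_sites=inner.source_sites, seed=seed,
                            quotas=quotas)

    n_target = max(1, int(round(test_subject_frac * len(subjects))))
    remaining = list(subjects)
    chosen: list[str] = []
    test_sbp = np.empty(0)
    max_extra = len(subjects) - 3  # leave >=1 subject for train/val/calib
    while len(chosen) < min(n_target, max_extra) or (
            not quotas.satisfied(test_sbp) and len(chosen) < max_extra):
        if not remaining:
            break
        f = quotas.fractions(test_sbp)
        deficits = {"low": quotas.low_frac - f["low"],
                    "high": quotas.high_frac - f["high"],
                    "mid": quotas.mid_frac - f["mid"]}
        worst = max(deficits, key=deficits.get)
        if deficits[worst] > 0 and len(test_sbp):
            key = {"low": lambda s: (store.sbp[groups[s]] <= quotas.low_threshold).mean(),
                   "high": lambda s: (store.sbp[groups[s]] >= quotas.high_threshold).mean(),
                   "mid": lambda s: (store.sbp[groups[s]] >= quotas.mid_threshold).mean()}[worst]
            scores = [key(s) for s in remaining]
            pick = int(np.argmax(scores))
        else:
            pick = 0
        s = remaining.pop(pick)
        chosen.append(s)
        test_sbp = np.concatenate([test_sbp, store.sbp[groups[s]]])
    if not quotas.satisfied(test_sbp):
        achieved = quotas.fractions(test_sbp)
        raise InfeasibleQuotaError(
            f"tail quotas unsatisfiable on this store; achieved fractions "
            f"{achieved} with {len(chosen)} test subjects", achieved)

    rest = np.array(remaining)
    n_val = max(1, int(round(val_subject_frac * len(subjects))))
    n_calib = max(1, int(round(calib_subject_frac * len(subjects))))
    while len(rest) - n_val - n_calib < 1:
        if n_calib > 1:
            n_calib -= 1
        else:
            n_val -= 1
    assign = {"test": np.array(chosen), "val": rest[:n_val],
              "calib": rest[n_val:n_val + n_calib], "train": rest[n_val + n_calib:]}
    parts = {k: np.sort(np.concatenate([groups[s] for s in v]))
             for k, v in assign.items()}
    return DatasetSplit(scenario="aami", **parts,
                        source_sites=sorted(np.unique(store.site_id).tolist()),
                        seed=seed, quotas=quotas)


def _check_fracs(*fracs):
    if any(f <= 0 for f in fracs) or sum(fracs) >= 1:
        raise SplitConfigurationError(
            f"fractions must be positive and sum to < 1, got {fracs}")


# ----------------------------------------------------------------------
def verify_split(store: SegmentStore, split: DatasetSplit) -> dict[str, bool]:
    """Per-invariant pass/fail report; raises only on out-of-range indices."""
    parts = split.parts()
    allidx = np.concatenate([v for v in parts.values() if len(v)]) \
        if any(len(v) for v in parts.values()) else np.empty(0, dtype=int)
    if allidx.size and (allidx.min() < 0 or allidx.max() >= store.n):
        raise IndexError("split contains out-of-range indices")
    report = {}
    sets = {k: set(v.tolist()) for k, v in parts.items()}
    report["disjoint"] = sum(len(s) for s in sets.values()) == len(
        set().union(*sets.values()))
    subj = {k: set(store.subject_id[v]) for k, v in parts.items()}
    if split.scenario == "calib":
        report["scenario_semantics"] = subj["test"] <= subj["train"]
    else:
        trainside = subj["train"] | subj["val"] | subj["calib"]
        report["scenario_semantics"] = not (trainside & subj["test"])
    if split.scenario == "aami" and split.quotas is not None:
        report["tail_quotas"] = split.quotas.satisfied(store.sbp[split.test])
    return report


def save_split(split: DatasetSplit, path) -> None:
    payload = {"scenario": split.scenario, "seed": split.seed,
               "source_sites": split.source_sites,
               "quotas": asdict(split.quotas) if split.quotas else None,
               "parts": {k: v.tolist() for k, v in split.parts().items()}}
    with open(path, "w") as f:
        json.dump(payload, f)


def load_split(path) -> DatasetSplit:
    with open(path) as f:
        payload = json.load(f)
    return DatasetSplit(scenario=payload["scenario"],
                        seed=payload["seed"],
                        source_sites=payload["source_sites"],
                        quotas=TailQuotas(**payload["quotas"])
                        if payload.get("quotas") else None,
                        **{k: np.asarray(v, dtype=np.intp)
                           for k, v in payload["parts"].items()})
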