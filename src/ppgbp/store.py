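"""Canonical data model for labeled PPG segments.

A :class:`SegmentStore` holds per-segment waveforms together with their
systolic/diastolic reference pressures (mmHg) and subject/site identity.
Waveform length may differ between sites (different recording
protocols) but is uniform within a site.  The on-disk format is an HDF5
container with one group per site, so signals are stored as dense 2-D
arrays without ragged storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["SegmentStore", "write_store", "read_store", "select",
           "StoreValidationError", "StoreFormatError"]

BP_MIN, BP_MAX = 20.0, 260.0
DEFAULT_FS = 125.0


class StoreValidationError(ValueError):
    """A store (or file contents) violates the segment-store invariants."""


class StoreFormatError(ValueError):
    """An on-disk container is missing required groups/fields."""


@dataclass
class SegmentStore:
    """In-memory container for labeled PPG segments.

    Parameters
    ----------
    signals : object ndarray of 1-D float arrays
        Raw (unnormalized) waveforms; uniform length within each site.
    fs : float
        Sampling frequency in Hz (125 Hz for all datasets emulated here).
    sbp, dbp : float64 arrays, mmHg
    subject_id, site_id : str arrays
    attrs : dict
        Free-form provenance metadata (e.g. the generator seed).
    """

    signals: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    subject_id: np.ndarray
    site_id: np.ndarray
    fs: float = DEFAULT_FS
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = _as_object_array([np.asarray(s, dtype=np.float64)
                                         for s in self.signals])
        self.sbp = np.asarray(self.sbp, dtype=np.float64)
        self.dbp = np.asarray(self.dbp, dtype=np.float64)
        self.subject_id = np.asarray(self.subject_id, dtype=str)
        self.site_id = np.asarray(self.site_id, dtype=str)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.signals)

    def __len__(self) -> int:
        return self.n

    def validate(self) -> None:
        n = self.n
        for name in ("sbp", "dbp", "subject_id", "site_id"):
            if len(getattr(self, name)) != n:
                raise StoreValidationError(
                    f"field {name!r} has length {len(getattr(self, name))}, expected {n}")
        if not self.fs > 0:
            raise StoreValidationError(f"fs must be positive, got {self.fs}")
        if n == 0:
            return
        if not (np.isfinite(self.sbp).all() and np.isfinite(self.dbp).all()):
            raise StoreValidationError("non-finite BP labels")
        if not (self.sbp > self.dbp).all():
            bad = np.flatnonzero(self.sbp <= self.dbp)[:5]
            raise StoreValidationError(f"sbp <= dbp at segments {bad.tolist()}")
        for arr, name in ((self.sbp, "sbp"), (self.dbp, "dbp")):
            if ((arr < BP_MIN) | (arr > BP_MAX)).any():
                raise StoreValidationError(
                    f"{name} outside [{BP_MIN}, {BP_MAX}] mmHg")
        for site in np.unique(self.site_id):
            lens = {len(s) for s in self.signals[self.site_id == site]}
            if len(lens) > 1:
                raise StoreValidationError(
                    f"site {site!r} has mixed segment lengths {sorted(lens)}")

    # ------------------------------------------------------------------
    def site_length(self, site: str) -> int:
        idx = np.flatnonzero(self.site_id == site)
        if idx.size == 0:
            raise KeyError(f"no segments for site {site!r}")
        return len(self.signals[idx[0]])

    def select(self, indices) -> "SegmentStore":
        return select(self, indices)

    def label_frame(self) -> pd.DataFrame:
        """Label table (site, subject, sbp, dbp) for inspection/CSV export."""
        return pd.DataFrame({"site": self.site_id, "subject": self.subject_id,
                             "sbp": self.sbp, "dbp": self.dbp})

    def write_labels_csv(self, path) -> None:
        self.label_frame().to_csv(path, index=False)

    def write(self, path) -> None:
        write_store(self, path)

    def equals(self, other: "SegmentStore") -> bool:
        return (self.n == other.n and self.fs == other.fs
                and np.array_equal(self.sbp, other.sbp)
                and np.array_equal(self.dbp, other.dbp)
                and np.array_equal(self.subject_id, other.subject_id)
                and np.array_equal(self.site_id, other.site_id)
                and all(np.array_equal(a, b)
                        for a, b in zip(self.signals, other.signals)))


def _as_object_array(items: list[np.ndarray]) -> np.ndarray:
    out = np.empty(len(items), dtype=object)
    for i, s in enumerate(items):
        out[i] = s
    return out


# ----------------------------------------------------------------------
def select(store: SegmentStore, indices) -> SegmentStore:
    """Sub-store in the given index order; duplicates allowed (bootstrap)."""
    indices = np.asarray(indices, dtype=np.intp)
    if indices.size and (indices.min() < 0 or indices.max() >= store.n):
        raise IndexError(f"index out of range [0, {store.n})")
    return SegmentStore(signals=store.signals[indices],
                        sbp=store.sbp[indices], dbp=store.dbp[indices],
                        subject_id=store.subject_id[indices],
                        site_id=store.site_id[indices],
                        fs=store.fs, attrs=dict(store.attrs))


def write_store(store: SegmentStore, path) -> None:
    """Write to HDF5: one group per site, file-level fs attribute.

    A per-site ``order`` dataset records each segment's position in the
    original store so that read-back restores the exact segment order.
    """
    store.validate()
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = store.fs
        f.attrs["n"] = store.n
        for k, v in store.attrs.items():
            f.attrs["meta." + str(k)] = v
        for site in np.unique(store.site_id):
            idx = np.flatnonzero(store.site_id == site)
            g = f.create_group(f"site/{site}")
            g.create_dataset("signals", data=np.stack(store.signals[idx].tolist())
                             if idx.size else np.zeros((0, 0)))
            g.create_dataset("sbp", data=store.sbp[idx])
            g.create_dataset("dbp", data=store.dbp[idx])
            g.create_dataset("subject",
                             data=np.char.encode(store.subject_id[idx], "utf-8"))
            g.create_dataset("order", data=idx)


def read_store(path) -> SegmentStore:
    """Inverse of :func:`write_store`; validates all invariants on read."""
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise StoreFormatError("missing file attribute 'fs'")
        fs = float(f.attrs["fs"])
        n = int(f.attrs.get("n", 0))
        attrs = {k[len("meta."):]: _plain(v) for k, v in f.attrs.items()
                 if k.startswith("meta.")}
        signals = np.empty(n, dtype=object)
        sbp = np.zeros(n)
        dbp = np.zeros(n)
        subject = np.empty(n, dtype=object)
        site_arr = np.empty(n, dtype=object)
        for site in (f["site"] if "site" in f else {}):
            g = f[f"site/{site}"]
            for req in ("signals", "sbp", "dbp", "subject", "order"):
                if req not in g:
                    raise StoreFormatError(
                        f"site group {site!r} missing dataset {req!r}")
            order = np.asarray(g["order"])
            sig = np.asarray(g["signals"], dtype=np.float64)
            if len(order) != len(sig) or len(order) != len(g["sbp"]):
                raise StoreFormatError(
                    f"site group {site!r} has mismatched array lengths")
            for row, pos in enumerate(order):
                signals[pos] = sig[row]
            sbp[order] = np.asarray(g["sbp"])
            dbp[order] = np.asarray(g["dbp"])
            subject[order] = np.char.decode(np.asarray(g["subject"]), "utf-8")
            site_arr[order] = site
        if n and any(s is None for s in signals):
            raise StoreFormatError("segment order table does not cover all segments")
    return SegmentStore(signals=signals, sbp=sbp, dbp=dbp,
                        subject_id=subject.astype(str) if n else np.empty(0, dtype=str),
                        site_id=site_arr.astype(str) if n else np.empty(0, dtype=str),
                        fs=fs, attrs=attrs)


def _plain(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v
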