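"""Peak tables, sample metadata and marker records: containers and TSV round-trip.

A :class:`PeakTable` is a features x samples intensity matrix with per-feature
retention time (minutes), m/z (Da) and chromatographic block (reversed-phase
``"RP"`` or hydrophilic-interaction ``"HILIC"``).  Intensities are non-negative;
an intensity of exactly 0 encodes a missing (undetected) value.

Sample metadata travels as a plain :class:`pandas.DataFrame` with the columns
in :data:`META_COLUMNS`; ``condition`` is one of ``treated``/``control``/``qc``
and pooled-QC rows carry no drug, class or cell count.

The packaged marker tables (one per drug class: microtubule-affecting,
DNA-acting, antimetabolite, RNA-interfering) are shipped as TSV fixtures and
loaded with :func:`load_marker_fixtures`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

BLOCKS = ("RP", "HILIC")

#: acquired m/z range per block, Da
BLOCK_MZ_RANGE = {"RP": (8.0, 1000.0), "HILIC": (124.0, 1000.0)}

#: canonical mechanism-of-action class labels, in study order
CLASS_LABELS = ("antimetabolite", "dna_acting", "microtubule", "rna_interference")

META_COLUMNS = (
    "sample_id",
    "cell_line",
    "drug",
    "moa_class",
    "condition",
    "cell_count",
    "injection_order",
)

CONDITIONS = ("treated", "control", "qc")

_FIXTURE_SHA256 = {
    "table2.tsv": "bb39a5fd84630106eb18145ea1da22e534c20d3af1e231b1778626adb5785c66",
    "table3.tsv": "25eb131808dc0a2cc704f7e55964114140eeddd32101a80f9ed53c2c0ee7ea92",
    "table4.tsv": "be7f802d7d3a62d745682dda5d26be073a3a0898a04a145218fa5787ed813a8b",
    "table5.tsv": "7679e86affc5a8f39eb3d25de274ab02799fc01114be92f9ff5c2270082346be",
}


class PeakTableError(ValueError):
    """Malformed peak table or metadata."""


def feature_id(block: str, rt: float, mz: float) -> str:
    """Canonical feature id: block-prefixed RT/mz pair, 3/4 decimals."""
    return f"{block}_{rt:.3f}_{mz:.4f}"


@dataclass
class PeakTable:
    """Aligned feature table for one chromatographic block.

    Parameters
    ----------
    features
        One row per feature, index = feature_id, columns ``block``, ``rt``
        (min) and ``mz`` (Da).
    intensities
        Features x samples matrix, same index as ``features``; columns are
        sample ids; values >= 0, with 0 meaning missing.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        feats = self.features
        if feats.index.has_duplicates:
            dup = feats.index[feats.index.duplicated()].unique().tolist()
            raise PeakTableError(f"duplicate feature_id(s): {dup}")
        if not feats.index.equals(self.intensities.index):
            raise PeakTableError("features and intensities indices differ")
        if len(feats) and (feats["rt"] <= 0).any():
            bad = feats.index[feats["rt"] <= 0].tolist()
            raise PeakTableError(f"non-positive retention time for {bad}")
        for block, sub in feats.groupby("block", observed=True):
            if block not in BLOCKS:
                raise PeakTableError(f"unknown block label {block!r}")
            lo, hi = BLOCK_MZ_RANGE[block]
            out = sub.index[(sub["mz"] < lo) | (sub["mz"] > hi)].tolist()
            if out:
                raise PeakTableError(
                    f"m/z outside acquired range {lo}-{hi} Da for block {block}: {out}"
                )
        vals = self.intensities.to_numpy()
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise PeakTableError("intensities must be finite and >= 0")

    # -- convenience --------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_samples(self, sample_ids) -> "PeakTable":
        return PeakTable(self.features.copy(), self.intensities.loc[:, list(sample_ids)].copy())

    def subset_features(self, feature_ids) -> "PeakTable":
        idx = list(feature_ids)
        return PeakTable(self.features.loc[idx].copy(), self.intensities.loc[idx].copy())

    def copy(self) -> "PeakTable":
        return PeakTable(self.features.copy(), self.intensities.copy())

    def equals(self, other: "PeakTable") -> bool:
        return self.features.equals(other.features) and self.intensities.equals(
            other.intensities
        )


@dataclass(frozen=True)
class MarkerRecord:
    """One differential metabolite, mirroring the printed per-class tables."""

    moa_class: str
    no: int
    rt: float
    name: str
    mz: float
    p_flag: str  # one of "<0.05", "<0.01", "<0.001"
    auc: float
    fc: float
    trend: str  # "up" or "down"
    pathway: str | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of [0,1]: {self.auc}")
        if self.fc <= 0:
            raise ValueError(f"fold change must be positive: {self.fc}")
        if self.trend not in ("up", "down"):
            raise ValueError(f"trend must be up/down: {self.trend}")
        if (self.fc > 1) != (self.trend == "up"):
            raise ValueError(
                f"trend/fold-change mismatch for {self.name}: fc={self.fc}, trend={self.trend}"
            )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_peak_table(table: PeakTable, path) -> None:
    """Write wide TSV: feature_id, block, rt_min, mz, then one column per sample."""
    out = table.features.copy()
    out.insert(0, "feature_id", out.index)
    out = out.rename(columns={"rt": "rt_min"})
    out = pd.concat([out.reset_index(drop=True),
                     table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    """Read a wide TSV written by :func:`write_peak_table`.

    Raises :class:`PeakTableError` naming the offending row/id on duplicate
    feature ids, negative intensities or malformed numerics.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "block": str})
    required = ["feature_id", "block", "rt_min", "mz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing column(s) {missing}")
    dup = df["feature_id"][df["feature_id"].duplicated()].unique().tolist()
    if dup:
        raise PeakTableError(f"{path}: duplicate feature_id(s) {dup}")
    sample_cols = [c for c in df.columns if c not in required]
    numeric = df[["rt_min", "mz"] + sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PeakTableError(f"{path}: malformed numeric value at data row {row + 1}")
    neg = (numeric[sample_cols] < 0).any(axis=1)
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0])
        raise PeakTableError(f"{path}: negative intensity at data row {row + 1}")
    features = pd.DataFrame(
        {"block": df["block"].to_numpy(), "rt": numeric["rt_min"].to_numpy(),
         "mz": numeric["mz"].to_numpy()},
        index=pd.Index(df["feature_id"], name="feature_id"),
    )
    intens = numeric[sample_cols].astype(float)
    intens.index = features.index
    return PeakTable(features, intens)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    validate_sample_meta(meta)
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str,
                                              "drug": str, "moa_class": str,
                                              "condition": str})
    validate_sample_meta(meta)
    return meta


def validate_sample_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise PeakTableError(f"sample metadata missing column(s) {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
        raise PeakTableError(f"duplicate sample_id(s): {dup}")
    bad = ~meta["condition"].isin(CONDITIONS)
    if bad.any():
        raise PeakTableError(
            f"unknown condition(s): {meta['condition'][bad].unique().tolist()}"
        )
    qc = meta["condition"] == "qc"
    if (qc & (meta["drug"].notna() | meta["moa_class"].notna())).any():
        raise PeakTableError("QC samples must carry no drug or class label")
    nonqc = meta.loc[~qc, "cell_count"]
    if nonqc.isna().any() or (nonqc <= 0).any():
        raise PeakTableError("non-QC samples need a positive cell_count")


# ---------------------------------------------------------------------------
# Packaged marker fixtures
# ---------------------------------------------------------------------------

def _fixture_dir():
    return resources.files("moaprofile").joinpath("data/fixtures")


def load_marker_fixtures(verify_checksum: bool = True) -> list[MarkerRecord]:
    """Load the packaged per-class marker tables as :class:`MarkerRecord` rows.

    The four files cover the microtubule-affecting, DNA-acting, antimetabolite
    and RNA-interfering drug classes (52 records in total).  A SHA-256 check
    guards against silent corruption of the packaged transcriptions.
    """
    records: list[MarkerRecord] = []
    for fname in sorted(_FIXTURE_SHA256):
        res = _fixture_dir().joinpath(fname)
        raw = res.read_bytes()
        if verify_checksum:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != _FIXTURE_SHA256[fname]:
                raise RuntimeError(f"fixture checksum mismatch for {fname}")
        df = pd.read_csv(res.open("r"), sep="\t").rename(columns={"class": "moa_class"})
        for row in df.itertuples(index=False):
            pathway = None if pd.isna(row.pathway) else str(row.pathway)
            records.append(
                MarkerRecord(
                    moa_class=str(row.moa_class),
                    no=int(row.no),
                    rt=float(row.rt),
                    name=str(row.name),
                    mz=float(row.mz),
                    p_flag=str(row.p_flag),
                    auc=float(row.auc),
                    fc=float(row.fc),
                    trend=str(row.trend),
                    pathway=pathway,
                )
            )
    return records


def marker_fixture_frame() -> pd.DataFrame:
    """Marker fixtures as a tidy DataFrame (one row per printed table row)."""
    recs = load_marker_fixtures()
    return pd.DataFrame([r.__dict__ for r in recs])


def filter_marker_records(
    records: list[MarkerRecord],
    min_auc: float = 0.50,
    alpha: float = 0.05,
) -> list[MarkerRecord]:
    """Apply the study's marker inclusion rule: AUC above ``min_auc`` (strict)
    and Bonferroni-adjusted significance below ``alpha``."""
    thresh = {"<0.05": 0.05, "<0.01": 0.01, "<0.001": 0.001}
    kept = []
    for r in records:
        if r.auc > min_auc and thresh[r.p_flag] <= alpha:
            kept.append(r)
    return kept


def unique_marker_names(records: list[MarkerRecord], key=lambda r: r.name.lower()) -> list[str]:
    """Deduplicate marker records across classes by ``key`` (default: name,
    case-insensitive), preserving first-seen order.

    The printed tables repeat several metabolites across classes and contain
    two distinct d-erythrose 4-phosphate ions; the dedup key is exposed so the
    caller decides what counts as "the same metabolite".
    """
    seen: dict[object, str] = {}
    for r in records:
        k = key(r)
        if k not in seen:
            seen[k] = r.name
    return list(seen.values())
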