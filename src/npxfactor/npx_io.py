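"""Reading, writing and pairing of Olink-style NPX data.

NPX (Normalized Protein eXpression) is Olink's relative abundance unit on a
log2 scale: a difference of 1 NPX corresponds to roughly a two-fold change in
protein concentration.  This module ingests the common long export format
(one row per sample x assay), pivots it to a samples-by-proteins matrix, and
aligns matched serum/plasma aliquots of the same subjects so that per-protein
cross-medium regressions can be fitted.

Column names in long exports vary between Olink software versions; the
defaults follow the usual convention (``SampleID``, ``OlinkID``, ``NPX``,
``QC_Warning``) and can be remapped through :class:`ColumnMap`.  Rows carrying
a QC warning are kept but flagged -- whether to exclude them is the caller's
decision, not this module's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, MappingError

logger = logging.getLogger(__name__)

MEDIA = ("serum", "plasma", "unknown")


@dataclass
class ColumnMap:
    """Mapping from long-format column names to their roles.

    ``protein`` selects the single identifier column used to key assays
    (OlinkID, UniProt or Assay name, whichever the caller prefers);
    cross-identifier reconciliation is out of scope.
    """

    sample: str = "SampleID"
    protein: str = "OlinkID"
    npx: str = "NPX"
    qc: str = "QC_Warning"


@dataclass
class NPXMatrix:
    """A samples x proteins table of log2-scale NPX values.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by sample ID, columns by protein/assay ID, float NPX.
        Missing measurements are NaN.
    medium : str
        One of ``serum``, ``plasma`` or ``unknown``.
    qc_flags : DataFrame, optional
        Boolean table of the same shape; True marks a QC-warned measurement.
    transformed : bool
        Set by :func:`npxfactor.catalog.apply_transform` on converted output.
    """

    values: pd.DataFrame
    medium: str = "unknown"
    qc_flags: pd.DataFrame | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ValueError(f"medium must be one of {MEDIA}, got {self.medium!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise IntegrityError(f"duplicate sample ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise IntegrityError(f"duplicate protein ID {dup!r}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric NPX value: {exc}") from exc
        if np.isinf(self.values.to_numpy()).any():
            raise FormatError("NPX values must be finite or missing (NaN)")
        if self.qc_flags is not None and self.qc_flags.shape != self.values.shape:
            raise IntegrityError("qc_flags shape does not match values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def to_long(self, columns: ColumnMap | None = None) -> pd.DataFrame:
        """Melt back to long format, dropping missing cells."""
        cm = columns or ColumnMap()
        long = (
            self.values.rename_axis(index=cm.sample, columns=cm.protein)
            .stack()
            .rename(cm.npx)
            .reset_index()
        )
        if self.qc_flags is not None:
            qc = self.qc_flags.rename_axis(index=cm.sample, columns=cm.protein)
            qc_long = qc.stack().rename(cm.qc).reset_index()
            long = long.merge(qc_long, on=[cm.sample, cm.protein], how="left")
            long[cm.qc] = np.where(long[cm.qc].fillna(False), "WARN", "PASS")
        return long


@dataclass
class MatchedCohort:
    """Paired serum and plasma matrices aligned on subjects.

    After construction both matrices are indexed by the serum-side sample ID
    (used as the subject label), carry the same subject ordering and the same
    protein set (the intersection of the two panels).
    """

    serum: NPXMatrix
    plasma: NPXMatrix
    subject_map: list = field(default_factory=list)
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.serum.n_samples < 3:
            raise IntegrityError(
                f"cohort {self.cohort_label!r}: fewer than 3 matched subjects"
            )
        if list(self.serum.values.index) != list(self.plasma.values.index):
            raise IntegrityError("serum/plasma subject ordering differs")
        if list(self.serum.values.columns) != list(self.plasma.values.columns):
            raise IntegrityError("serum/plasma protein sets differ")

    @property
    def subject_ids(self) -> list:
        return list(self.serum.values.index)

    @property
    def protein_ids(self) -> list:
        return list(self.serum.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.serum.n_samples


def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table, sniffing the delimiter (comma or tab)."""
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_npx_long(path, medium: str = "unknown", columns: ColumnMap | None = None) -> NPXMatrix:
    """Read a long-format NPX export and pivot it to a wide matrix.

    Mandatory columns are the sample ID, the protein ID and the NPX value
    (names per ``columns``); a QC-warning column is optional and, when
    present, any non-empty value other than ``PASS``/``0``/``False`` marks
    the measurement as warned.  Duplicate (sample, protein) rows are an
    error -- the pivot never aggregates.
    """
    cm = columns or ColumnMap()
    df = _read_table(path)
    for col in (cm.sample, cm.protein, cm.npx):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    dup = df.duplicated(subset=[cm.sample, cm.protein])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise IntegrityError(
            f"duplicated (sample, protein) pair ({row[cm.sample]!r}, {row[cm.protein]!r})"
        )
    try:
        npx = pd.to_numeric(df[cm.npx], errors="raise")
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric NPX value in {path}: {exc}") from exc
    df = df.assign(**{cm.npx: npx})
    wide = df.pivot(index=cm.sample, columns=cm.protein, values=cm.npx)
    wide = wide.rename_axis(index=None, columns=None)
    qc_flags = None
    if cm.qc in df.columns:
        warned = ~df[cm.qc].astype(str).str.strip().isin(["", "PASS", "Pass", "0", "False", "nan"])
        qc_flags = (
            df.assign(_warn=warned)
            .pivot(index=cm.sample, columns=cm.protein, values="_warn")
            .rename_axis(index=None, columns=None)
            .fillna(False)
            .astype(bool)
        )
    return NPXMatrix(values=wide, medium=medium, qc_flags=qc_flags)


def read_npx_wide(path, medium: str = "unknown") -> NPXMatrix:
    """Read a wide CSV/TSV: first column sample ID, remaining columns proteins."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise FormatError(f"wide NPX table {path} needs a sample column plus proteins")
    df = df.set_index(df.columns[0])
    df.index.name = None
    return NPXMatrix(values=df, medium=medium)


def write_npx_long(matrix: NPXMatrix, path, columns: ColumnMap | None = None) -> None:
    matrix.to_long(columns).to_csv(path, sep="\t", index=False, float_format="%.10g")


def pair_matched(
    serum: NPXMatrix,
    plasma: NPXMatrix,
    subject_map: list | None = None,
    cohort_label: str = "",
) -> MatchedCohort:
    """Align matched serum and plasma aliquots into a :class:`MatchedCohort`.

    ``subject_map`` is a list of ``(serum_sample_id, plasma_sample_id)``
    pairs; when omitted, sample IDs shared verbatim between the two matrices
    are paired.  Proteins are restricted to the panel intersection (serum
    column order preserved); proteins left with zero complete (serum, plasma)
    pairs are dropped with a warning.
    """
    if serum.n_samples == 0 or plasma.n_samples == 0:
        raise IntegrityError("empty NPX matrix")
    if subject_map is None:
        shared = [s for s in serum.sample_ids if s in set(plasma.sample_ids)]
        subject_map = [(s, s) for s in shared]
    if not subject_map:
        raise MappingError("subject map is empty and no sample IDs are shared")
    serum_index = set(serum.sample_ids)
    plasma_index = set(plasma.sample_ids)
    for s_id, p_id in subject_map:
        if s_id not in serum_index:
            raise MappingError(f"serum sample {s_id!r} not found")
        if p_id not in plasma_index:
            raise MappingError(f"plasma sample {p_id!r} not found")
    proteins = [p for p in serum.protein_ids if p in set(plasma.protein_ids)]
    if not proteins:
        raise IntegrityError("serum and plasma panels share no proteins")
    s_ids = [s for s, _ in subject_map]
    p_ids = [p for _, p in subject_map]
    s_vals = serum.values.loc[s_ids, proteins]
    p_vals = plasma.values.loc[p_ids, proteins].set_axis(s_ids, axis=0)
    complete = (s_vals.notna() & p_vals.notna()).sum(axis=0)
    empty = complete[complete == 0].index
    if len(empty):
        logger.warning(
            "dropping %d protein(s) with no complete serum/plasma pair: %s",
            len(empty), ", ".join(map(str, empty[:5])) + ("..." if len(empty) > 5 else ""),
        )
        keep = [p for p in proteins if p not in set(empty)]
        s_vals = s_vals[keep]
        p_vals = p_vals[keep]
    return MatchedCohort(
        serum=NPXMatrix(s_vals, medium="serum"),
        plasma=NPXMatrix(p_vals, medium="plasma"),
        subject_map=list(subject_map),
        cohort_label=cohort_label,
    )


# ---------------------------------------------------------------------------
# Factor-catalog serialisation

_FACTOR_COLUMNS = [
    "protein_id", "slope", "intercept", "slope_se", "ci_halfwidth", "r2",
    "tier", "n_used", "excluded_samples", "cohort_label", "direction",
]


def write_factor_table(catalog, path) -> None:
    """Write a :class:`~npxfactor.catalog.FactorCatalog` as TSV.

    Floats are serialised with 10 significant digits so a written-then-read
    catalog is value-identical well past the documented 6-digit precision.
    Catalog-level metadata (gate threshold, provenance) travels in a leading
    comment line.
    """
    rows = []
    for f in catalog:
        rows.append({
            "protein_id": f.protein_id,
            "slope": f.slope,
            "intercept": f.intercept,
            "slope_se": f.slope_se,
            "ci_halfwidth": f.ci_halfwidth,
            "r2": f.r2,
            "tier": f.tier,
            "n_used": f.n_used,
            "excluded_samples": ";".join(map(str, f.excluded_samples)),
            "cohort_label": f.cohort_label,
            "direction": f.direction,
        })
    df = pd.DataFrame(rows, columns=_FACTOR_COLUMNS)
    gate = catalog.gate_threshold
    prov = ",".join(catalog.provenance)
    with open(path, "w") as fh:
        fh.write(f"# npxfactor-catalog\tgate_threshold={'' if gate is None else repr(gate)}\tprovenance={prov}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_factor_table(path):
    """Inverse of :func:`write_factor_table`."""
    from .catalog import FactorCatalog, TransformationFactor

    gate = None
    provenance: list[str] = []
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split("\t"):
            token = token.strip()
            if token.startswith("gate_threshold=") and token != "gate_threshold=":
                gate = float(token.split("=", 1)[1])
            elif token.startswith("provenance="):
                prov = token.split("=", 1)[1]
                provenance = [p for p in prov.split(",") if p]
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"factor table {path} missing column(s) {missing}")
    factors = []
    for _, row in df.iterrows():
        excl = row["excluded_samples"]
        excluded = [] if pd.isna(excl) or excl == "" else str(excl).split(";")
        factors.append(TransformationFactor(
            protein_id=row["protein_id"],
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            slope_se=float(row["slope_se"]),
            ci_halfwidth=float(row["ci_halfwidth"]),
            r2=float(row["r2"]),
            tier=int(row["tier"]),
            n_used=int(row["n_used"]),
            excluded_samples=excluded,
            cohort_label="" if pd.isna(row["cohort_label"]) else str(row["cohort_label"]),
            direction=str(row["direction"]),
        ))
    return FactorCatalog(factors=factors, gate_threshold=gate, provenance=provenance)
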