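"""Readers and writers for MaxQuant-dialect tables, motif tables and FASTA.

Two reporter-column dialects are accepted: the raw MaxQuant form
``Reporter intensity corrected <label>`` and the dotted R-style form
``Reporter.intensity.corrected.<label>`` produced when such tables round-trip
through data frames.  Phospho-site reporter columns additionally carry a
``___<multiplicity>`` suffix; only the singly-phosphorylated ``___1``
intensities are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import MotifPattern, SiteWindow, parse_motif

log = logging.getLogger(__name__)

#: Candidate templates for reporter-intensity columns; ``{label}`` is the
#: channel label from the sample design, ``{suffix}`` the multiplicity tag
#: (empty for protein tables, ``___1`` for singly-phosphorylated sites).
REPORTER_TEMPLATES = (
    "Reporter intensity corrected {label}{suffix}",
    "Reporter.intensity.corrected.{label}{suffix}",
)

ENRICHMENTS = ("N", "PE")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class TableParseError(ValueError):
    """A cell value could not be parsed."""


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Per-channel metadata for one multiplexed experiment.

    ``table`` columns: channel_label, strain, replicate (doubles as the
    batch id), timepoint_min, enrichment (``N`` = total extract,
    ``PE`` = phospho-enriched).
    """

    table: pd.DataFrame

    REQUIRED = ("channel_label", "strain", "replicate", "timepoint_min",
                "enrichment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"sample design lacks columns: {missing}")
        t = self.table
        if (t["timepoint_min"] < 0).any():
            raise ValueError("timepoints must be nonnegative minutes")
        if not t["enrichment"].isin(ENRICHMENTS).all():
            bad = sorted(set(t["enrichment"]) - set(ENRICHMENTS))
            raise ValueError(f"unknown enrichment values: {bad}")
        for enr, sub in t.groupby("enrichment"):
            if sub["channel_label"].duplicated().any():
                dup = sub.loc[sub["channel_label"].duplicated(),
                              "channel_label"].tolist()
                raise ValueError(f"duplicate channel labels in {enr}: {dup}")
        # every (strain, replicate, enrichment) must cover one common
        # timepoint set
        tp_sets = {
            key: frozenset(sub["timepoint_min"])
            for key, sub in t.groupby(["strain", "replicate", "enrichment"])
        }
        if len(set(tp_sets.values())) > 1:
            raise ValueError(
                "all (strain, replicate) series must cover the same "
                f"timepoint set, got {sorted(map(sorted, set(tp_sets.values())))}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def timepoints(self) -> tuple[int, ...]:
        return tuple(sorted(self.table["timepoint_min"].unique()))

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.table["strain"]))

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(sorted(self.table["replicate"].unique()))

    def channels(
        self,
        enrichment: str | None = None,
        strain: str | None = None,
        replicate: int | None = None,
        timepoint: int | None = None,
    ) -> list[str]:
        """Channel labels matching the given selectors, in design order."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if enrichment is not None:
            mask &= t["enrichment"] == enrichment
        if strain is not None:
            mask &= t["strain"] == strain
        if replicate is not None:
            mask &= t["replicate"] == replicate
        if timepoint is not None:
            mask &= t["timepoint_min"] == timepoint
        return t.loc[mask, "channel_label"].tolist()

    def subset(self, enrichment: str) -> pd.DataFrame:
        return self.table[self.table["enrichment"] == enrichment].reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    protein_id: str
    intensities: np.ndarray  # aligned to design channel order
    gene_name: str = ""
    is_contaminant: bool = False
    is_reverse: bool = False


@dataclass
class PhosphoSiteRecord:
    protein_id: str
    position: int  # 1-based residue index in the protein
    residue: str
    localization_prob: float
    window: SiteWindow
    intensities: np.ndarray  # ___1 intensities aligned to design order
    multiplicity: int = 1
    gene_name: str = ""
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError(
                f"localization probability {self.localization_prob} "
                "outside [0, 1]"
            )
        center = self.window.center
        if center != "_" and center != self.residue:
            raise ValueError(
                f"window center {center!r} disagrees with residue "
                f"{self.residue!r}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}_{self.residue}{self.position}"


def _flag(series: pd.Series | None, n: int) -> np.ndarray:
    if series is None:
        return np.zeros(n, dtype=bool)
    return series.fillna("").astype(str).str.strip().eq("+").to_numpy()


def _find_column(df: pd.DataFrame, names: Sequence[str]) -> str | None:
    for name in names:
        if name in df.columns:
            return name
        dotted = name.replace(" ", ".")
        if dotted in df.columns:
            return dotted
    return None


def _reporter_columns(
    df: pd.DataFrame,
    labels: Sequence[str],
    suffix: str = "",
    template: str | None = None,
) -> list[str]:
    """Resolve reporter columns for the designed labels, trying each dialect."""
    templates = (template,) if template else REPORTER_TEMPLATES
    best_missing: list[str] | None = None
    for tmpl in templates:
        cols = [tmpl.format(label=lab, suffix=suffix) for lab in labels]
        missing = [lab for lab, c in zip(labels, cols) if c not in df.columns]
        if not missing:
            return cols
        if best_missing is None or len(missing) < len(best_missing):
            best_missing = missing
    raise SchemaError(
        f"reporter columns missing for channels {best_missing} "
        f"(suffix {suffix!r})"
    )


def _numeric_block(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    block = df[list(cols)].apply(pd.to_numeric, errors="coerce")
    bad = block.isna() & df[list(cols)].notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        col = bad.columns[int(np.argwhere(bad.to_numpy())[0][1])]
        raise TableParseError(
            f"non-numeric intensity at row {row}, column {col!r}"
        )
    return block.fillna(0.0).to_numpy(dtype=float)


def read_protein_table(
    path: str | Path,
    design: SampleDesign,
    enrichment: str = "N",
    template: str | None = None,
) -> list[ProteinRecord]:
    """Read a proteinGroups-style table aligned to the design's channels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = _find_column(df, ("Majority protein IDs", "Protein IDs",
                               "Protein"))
    if id_col is None:
        raise SchemaError("no protein id column (Majority protein IDs)")
    labels = design.channels(enrichment=enrichment)
    cols = _reporter_columns(df, labels, template=template)
    values = _numeric_block(df, cols)
    gene_col = _find_column(df, ("Gene names",))
    contam = _find_column(df, ("Potential contaminant", "Contaminant"))
    reverse = _find_column(df, ("Reverse",))
    is_contam = _flag(df[contam] if contam else None, len(df))
    is_rev = _flag(df[reverse] if reverse else None, len(df))
    genes = (df[gene_col].fillna("") if gene_col
             else pd.Series([""] * len(df)))
    records = []
    for i in range(len(df)):
        # a proteinGroups row may list several majority ids; match on the
        # leading accession and log the ambiguity
        raw_id = str(df[id_col].iloc[i])
        pid = raw_id.split(";")[0].strip()
        if ";" in raw_id:
            log.debug("row %d: multiple majority ids %r, using %r",
                      i, raw_id, pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                gene_name=str(genes.iloc[i]),
                intensities=values[i],
                is_contaminant=bool(is_contam[i]),
                is_reverse=bool(is_rev[i]),
            )
        )
    return records


def read_phospho_table(
    path: str | Path,
    design: SampleDesign,
    enrichment: str = "PE",
    template: str | None = None,
) -> list[PhosphoSiteRecord]:
    """Read a Phospho(STY)Sites-style table.

    Only singly-phosphorylated (``___1``) reporter intensities are retained;
    higher-multiplicity columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = _find_column(df, ("Protein", "Proteins", "Majority protein IDs"))
    if id_col is None:
        raise SchemaError("no protein id column in phospho table")
    pos_col = _find_column(df, ("Position", "Positions within proteins"))
    if pos_col is None:
        raise SchemaError("no Position column in phospho table")
    loc_col = _find_column(df, ("Localization prob",))
    if loc_col is None:
        raise SchemaError("no Localization prob column in phospho table")
    win_col = _find_column(df, ("Sequence window",))
    if win_col is None:
        raise SchemaError("no Sequence window column in phospho table")
    labels = design.channels(enrichment=enrichment)
    cols = _reporter_columns(df, labels, suffix="___1", template=template)
    values = _numeric_block(df, cols)
    contam = _find_column(df, ("Potential contaminant", "Contaminant"))
    reverse = _find_column(df, ("Reverse",))
    gene_col = _find_column(df, ("Gene names",))
    is_contam = _flag(df[contam] if contam else None, len(df))
    is_rev = _flag(df[reverse] if reverse else None, len(df))
    genes = (df[gene_col].fillna("") if gene_col
             else pd.Series([""] * len(df)))
    records = []
    for i in range(len(df)):
        loc = float(df[loc_col].iloc[i])
        if not 0.0 <= loc <= 1.0:
            raise ValueError(
                f"row {i}: localization probability {loc} outside [0, 1]"
            )
        window_seq = str(df[win_col].iloc[i]).split(";")[0].strip()
        if len(window_seq) % 2 != 1:
            raise TableParseError(
                f"row {i}: even-length sequence window {window_seq!r}"
            )
        window = SiteWindow(window_seq)
        records.append(
            PhosphoSiteRecord(
                protein_id=str(df[id_col].iloc[i]).split(";")[0].strip(),
                position=int(float(df[pos_col].iloc[i])),
                residue=window.center,
                localization_prob=loc,
                window=window,
                intensities=values[i],
                gene_name=str(genes.iloc[i]),
                is_contaminant=bool(is_contam[i]),
                is_reverse=bool(is_rev[i]),
            )
        )
    return records


def read_motif_table(path: str | Path) -> list[MotifPattern]:
    """Read a two-column (pattern TAB kinase-name) motif table."""
    patterns: list[MotifPattern] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(
                    f"line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            text, name = parts[0].strip(), parts[1].strip()
            if lineno == 1 and text.lower() in ("pattern", "motif"):
                continue  # optional header
            if name in seen:
                raise ValueError(f"line {lineno}: duplicate kinase {name!r}")
            seen.add(name)
            patterns.append(parse_motif(text, name))
    return patterns


def write_motif_table(patterns: Sequence[MotifPattern],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(f"{p.pattern_text}\t{p.name}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an id -> uppercase-sequence map (id = first header token)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        sequences[rec.id] = seq
    return sequences


def read_gene_name_map(path: str | Path) -> dict[str, str]:
    """Optional two-column systematic-name -> common-name table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["oln", "gene"])
    return dict(zip(df["oln"].astype(str), df["gene"].astype(str)))


# ---------------------------------------------------------------------------
# Frame conversion and output writers
# ---------------------------------------------------------------------------


def protein_frame(
    records: Sequence[ProteinRecord], design: SampleDesign,
    enrichment: str = "N",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(intensity matrix, metadata) indexed by protein id.

    Duplicate ids are disambiguated pandas-style by keeping the first and
    logging; in practice MaxQuant protein groups are unique.
    """
    labels = design.channels(enrichment=enrichment)
    ids, rows, meta = [], [], []
    seen = set()
    for r in records:
        if r.protein_id in seen:
            log.warning("duplicate protein id %s: keeping first", r.protein_id)
            continue
        seen.add(r.protein_id)
        ids.append(r.protein_id)
        rows.append(r.intensities)
        meta.append({"gene_name": r.gene_name,
                     "is_contaminant": r.is_contaminant,
                     "is_reverse": r.is_reverse})
    matrix = pd.DataFrame(np.asarray(rows, dtype=float), index=ids,
                          columns=labels)
    matrix.index.name = "protein_id"
    meta_df = pd.DataFrame(meta, index=matrix.index)
    return matrix, meta_df


def phospho_frame(
    records: Sequence[PhosphoSiteRecord], design: SampleDesign,
    enrichment: str = "PE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(intensity matrix, metadata incl. windows) indexed by site id."""
    labels = design.channels(enrichment=enrichment)
    ids, rows, meta = [], [], []
    seen = set()
    for r in records:
        sid = r.site_id
        if sid in seen:
            log.warning("duplicate site id %s: keeping first", sid)
            continue
        seen.add(sid)
        ids.append(sid)
        rows.append(r.intensities)
        meta.append({
            "protein_id": r.protein_id,
            "position": r.position,
            "residue": r.residue,
            "localization_prob": r.localization_prob,
            "window": r.window,
            "gene_name": r.gene_name,
            "is_contaminant": r.is_contaminant,
            "is_reverse": r.is_reverse,
        })
    matrix = pd.DataFrame(np.asarray(rows, dtype=float), index=ids,
                          columns=labels)
    matrix.index.name = "site_id"
    meta_df = pd.DataFrame(meta, index=matrix.index)
    return matrix, meta_df


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = True) -> None:
    """Write any result table as TSV with a stable header."""
    df.to_csv(path, sep="\t", index=index)


def write_protein_table(
    matrix: pd.DataFrame, meta: pd.DataFrame, path: str | Path,
    template: str = REPORTER_TEMPLATES[0],
) -> None:
    """Emit a proteinGroups-dialect TSV readable by :func:`read_protein_table`."""
    out = pd.DataFrame({"Majority protein IDs": matrix.index})
    out["Gene names"] = meta["gene_name"].to_numpy()
    for label in matrix.columns:
        out[template.format(label=label, suffix="")] = matrix[label].to_numpy()
    out["Reverse"] = np.where(meta["is_reverse"].to_numpy(), "+", "")
    out["Potential contaminant"] = np.where(
        meta["is_contaminant"].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)


def write_phospho_table(
    matrix: pd.DataFrame, meta: pd.DataFrame, path: str | Path,
    template: str = REPORTER_TEMPLATES[0],
    extra_multiplicity: Mapping[int, pd.DataFrame] | None = None,
) -> None:
    """Emit a Phospho(STY)Sites-dialect TSV readable by
    :func:`read_phospho_table`.

    ``extra_multiplicity`` optionally supplies ``___2``/``___3`` intensity
    matrices, written alongside the ``___1`` columns as MaxQuant does.
    """
    out = pd.DataFrame({"Protein": meta["protein_id"].to_numpy()})
    out["Position"] = meta["position"].to_numpy()
    out["Amino acid"] = meta["residue"].to_numpy()
    out["Localization prob"] = meta["localization_prob"].to_numpy()
    out["Sequence window"] = [w.sequence for w in meta["window"]]
    out["Gene names"] = meta["gene_name"].to_numpy()
    for label in matrix.columns:
        out[template.format(label=label, suffix="___1")] = (
            matrix[label].to_numpy())
    for mult, extra in (extra_multiplicity or {}).items():
        for label in extra.columns:
            out[template.format(label=label, suffix=f"___{mult}")] = (
                extra[label].to_numpy())
    out["Reverse"] = np.where(meta["is_reverse"].to_numpy(), "+", "")
    out["Potential contaminant"] = np.where(
        meta["is_contaminant"].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)
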