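"""Tabular interchange formats for the three-condition skin-proteome pipeline.

The pipeline starts *after* peptide-to-protein roll-up: its inputs are
protein-by-sample abundance tables (one per quantification channel — MS1
intensity and spectral count) plus a design sheet mapping each sample column
to a condition (``H`` healthy, ``NL`` non-lesional, ``L`` lesional), a
replicate/pool identifier and a channel.  All interchange files are
tab-separated UTF-8 with a header row; missing values may be written as an
empty cell, ``NA`` or ``NaN`` and are always written back as empty cells.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("H", "NL", "L")
CHANNELS = ("intensity", "spectral_count")

_NA_TOKENS = ["", "NA", "NaN", "nan"]


class FormatError(ValueError):
    """A file does not conform to the interchange format."""


class ValidationError(ValueError):
    """Parsed data violate a type invariant (negative value, duplicate id...)."""


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata: condition, replicate (pooled experiment), channel."""

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    channel: str = "intensity"

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition(s): {sorted(bad)}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel: {self.channel!r}")
        if not (len(self.sample_ids) == len(self.conditions) == len(self.replicate_ids)):
            raise ValidationError("design fields must have equal length")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]

    def require_conditions(self, needed: Iterable[str] = CONDITIONS) -> None:
        missing = [c for c in needed if c not in self.conditions]
        if missing:
            raise ValidationError(
                f"condition(s) {missing} absent from design; a tri-contrast run "
                f"needs all of {list(CONDITIONS)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "condition": self.conditions,
                "replicate_id": self.replicate_ids,
                "channel": self.channel,
            }
        )


@dataclass
class AbundanceMatrix:
    """Protein x sample abundances for one quantification channel.

    ``values`` is a proteins-in-rows DataFrame whose columns follow
    ``design.sample_ids``; missing cells are NaN; all observed values are
    nonnegative, and integer-valued for the spectral-count channel.  Matrices
    derived from raw counts (e.g. after per-sample normalization) may be
    fractional; they carry ``values.attrs['derived'] = True`` and skip the
    integrality check.
    """

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein id(s): {dup}")
        if list(self.values.columns) != list(self.design.sample_ids):
            raise ValidationError("value columns do not match design sample_ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative abundance values are not allowed")
        if self.design.channel == "spectral_count" and not self.values.attrs.get("derived"):
            obs = vals[~np.isnan(vals)]
            if not np.allclose(obs, np.round(obs)):
                raise ValidationError("spectral_count channel must be integer-valued")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.design.samples_for(condition)]


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (GO-like): id, free-text name/category, members."""

    term_id: str
    term_name: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"term {self.term_id}: empty member set")


@dataclass(frozen=True)
class ContrastCall:
    """Fold change plus significance flag for one pairwise contrast."""

    fc_ratio: float | None
    significant: bool

    @property
    def log2fc(self) -> float:
        if self.fc_ratio is None or not np.isfinite(self.fc_ratio) or self.fc_ratio <= 0:
            return float("nan")
        return float(np.log2(self.fc_ratio))


@dataclass(frozen=True)
class TriContrast:
    """The three contrasts for one protein: L vs H, NL vs H, NL vs L."""

    protein_id: str
    lh: ContrastCall
    nlh: ContrastCall
    nll: ContrastCall


def read_design(path: str | Path, channel: str | None = None) -> SampleDesign:
    """Read a design sheet (TSV: sample_id, condition, replicate_id, channel).

    If ``channel`` is given, only that channel's rows are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "replicate_id", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design sheet missing column(s): {sorted(missing)}")
    if channel is not None:
        df = df[df["channel"] == channel]
        if df.empty:
            raise FormatError(f"design sheet has no rows for channel {channel!r}")
    channels = df["channel"].unique().tolist()
    if len(channels) != 1:
        raise FormatError(
            f"design sheet mixes channels {channels}; pass channel= to select one"
        )
    return SampleDesign(
        sample_ids=tuple(df["sample_id"]),
        conditions=tuple(df["condition"]),
        replicate_ids=tuple(df["replicate_id"]),
        channel=channels[0],
    )


def read_abundance_table(
    path: str | Path,
    design_path: str | Path,
    channel: str | None = None,
) -> AbundanceMatrix:
    """Read a protein x sample TSV against its design sheet.

    First column is the protein id; every remaining column must be declared in
    the design sheet.  Blank / ``NA`` / ``NaN`` cells become missing values.
    Row order is preserved.
    """
    design = read_design(design_path, channel=channel)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate protein id(s) in {path}: {dup}")
    unknown = [c for c in df.columns if c not in design.sample_ids]
    if unknown:
        raise FormatError(f"column(s) {unknown} in {path} absent from design sheet")
    absent = [s for s in design.sample_ids if s not in df.columns]
    if absent:
        raise FormatError(f"design sample(s) {absent} absent from {path}")
    df = df[list(design.sample_ids)].astype(float)
    return AbundanceMatrix(values=df, design=design)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write the value grid as TSV (missing cells written empty)."""
    matrix.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def write_design(designs: Sequence[SampleDesign], path: str | Path) -> None:
    pd.concat([d.to_frame() for d in designs]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Read a GMT gene-set file: term, description, tab-separated members.

    Duplicate members within a line are collapsed; empty lines are skipped.
    """
    out: list[AnnotationSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, term_name = fields[0], fields[1]
            if term_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate term id {term_id}")
            seen.add(term_id)
            members = frozenset(m for m in fields[2:] if m)
            out.append(AnnotationSet(term_id, term_name, members))
    return out


def write_gmt(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.member_ids)]) + "\n")


def load_table2_fixture() -> list[tuple[str, TriContrast]]:
    """The 11 classic psoriasis biomarkers with their printed fold-change triplets.

    Fold changes are L vs H, NL vs H and NL vs L ratios as published for the
    study's biomarker panel (AKR1B10, CSTA, FABP5, PI3, the S100 family, SCCA2,
    STAT1/3); the ``significant`` flags encode the published per-contrast
    significance marks.
    """
    ref = importlib.resources.files("tritrend").joinpath("data/table2_biomarkers.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"protein_id": str})
    out = []
    for row in df.itertuples(index=False):
        tc = TriContrast(
            protein_id=row.protein_id,
            lh=ContrastCall(float(row.fc_LH), bool(row.sig_LH)),
            nlh=ContrastCall(float(row.fc_NLH), bool(row.sig_NLH)),
            nll=ContrastCall(float(row.fc_NLL), bool(row.sig_NLL)),
        )
        out.append((row.protein_id, tc))
    return out
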