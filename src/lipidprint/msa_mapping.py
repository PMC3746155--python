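"""Project per-structure contact frequencies onto a family sequence alignment.

Each structure's per-residue contact fractions are threaded onto its row of
a multiple sequence alignment (which is always an input — this package
never computes alignments), so that the k-th non-gap column of the row
receives the k-th residue's value and gap columns stay empty.  Averaging
the projected rows column-wise over the family measures how conserved a
lipid contact position is; crystal-derived 0/1 rows can be mixed in and
are flagged.  Unresolved residues are gap-marked, never zero-filled, so
missing data does not dilute apparent conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.SeqUtils import seq1

from .contacts import ContactProfile

__all__ = [
    "AlignmentProjection",
    "read_alignment",
    "map_profile_to_alignment",
    "strip_gaps",
    "aggregate_family",
    "projection_to_html",
]

GAP_CHARS = "-."


def read_alignment(path, fmt: str | None = None) -> list:
    """Read a FASTA or Clustal alignment into [(sequence_id, gapped_seq)].

    The format is inferred from the extension when not given (.fasta/.fa ->
    fasta, .aln/.clustal/.clw -> clustal).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fasta": "fasta", ".fa": "fasta", ".afa": "fasta",
               ".aln": "clustal", ".clustal": "clustal",
               ".clw": "clustal"}.get(suffix, "fasta")
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return rows


def _profile_sequence(profile: ContactProfile) -> str:
    """One-letter sequence of the profile's residues, in profile order."""
    return "".join(seq1(rn.capitalize()) if len(rn) == 3 else "X"
                   for rn in profile.data["resname"])


def map_profile_to_alignment(row_seq: str, profile: ContactProfile,
                             channel: str = "headgroup",
                             offset: int = 0) -> np.ndarray:
    """Thread a profile's channel values onto one gapped alignment row.

    The row's ungapped sequence must match the profile's residue sequence
    (one-letter codes) starting at ``offset`` into the profile; a mismatch
    reports the first differing position.  Returns one value per alignment
    column, NaN at gaps.
    """
    ungapped = [c for c in row_seq if c not in GAP_CHARS]
    seq = _profile_sequence(profile)[offset:offset + len(ungapped)]
    if len(seq) != len(ungapped):
        raise ValueError(
            f"row has {len(ungapped)} residues but the profile provides "
            f"{len(seq)} from offset {offset}; supply an offset/range")
    for k, (a, b) in enumerate(zip(ungapped, seq)):
        if a != b and a != "X" and b != "X":
            raise ValueError(
                f"sequence mismatch at ungapped position {k + 1}: "
                f"alignment has {a!r}, profile has {b!r}")
    values = profile.channel(channel).to_numpy(dtype=float)[
        offset:offset + len(ungapped)]
    out = np.full(len(row_seq), np.nan)
    k = 0
    for i, c in enumerate(row_seq):
        if c not in GAP_CHARS:
            out[i] = values[k]
            k += 1
    return out


def strip_gaps(row_seq: str, values: np.ndarray) -> np.ndarray:
    """Inverse of projection: the values at non-gap columns, in order."""
    return np.asarray([v for c, v in zip(row_seq, values) if c not in GAP_CHARS])


@dataclass
class AlignmentProjection:
    """Per-(sequence, column) contact values over one alignment.

    values: DataFrame indexed by sequence id, one column per alignment
    position (NaN = gap); column_means: family mean over non-gap entries
    (NaN where every row is gapped); binary_rows: ids of 0/1 crystal rows;
    annotations: optional column label map (e.g. helix names H1..H6).
    """

    alignment: list
    values: pd.DataFrame
    column_means: pd.Series
    binary_rows: set = field(default_factory=set)
    annotations: dict | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.binary_rows:
                fh.write("# binary_rows=" + ",".join(sorted(self.binary_rows)) + "\n")
            out = self.values.copy()
            out.loc["__family_mean__"] = self.column_means
            out.to_csv(fh, sep="\t", index_label="sequence", na_rep="")


def aggregate_family(alignment: list, projections: dict,
                     binary_rows: set | None = None,
                     annotations: dict | None = None) -> AlignmentProjection:
    """Combine per-row projections into a family table with column means.

    ``projections`` maps sequence id -> per-column value array; every array
    must have the alignment length and its NaNs must coincide with that
    row's gaps.  Means are taken over non-gap entries only, so a gap never
    dilutes a conserved column.
    """
    ids = {sid for sid, _ in alignment}
    length = len(alignment[0][1])
    rows = {}
    seqs = dict(alignment)
    for sid, vals in projections.items():
        if sid not in ids:
            raise ValueError(f"projection id {sid!r} not in the alignment")
        vals = np.asarray(vals, dtype=float)
        if len(vals) != length:
            raise ValueError(
                f"projection {sid!r} has length {len(vals)}, alignment has {length}")
        gaps = np.array([c in GAP_CHARS for c in seqs[sid]])
        if np.any(np.isnan(vals) != gaps):
            raise ValueError(f"projection {sid!r} NaNs do not match its gaps")
        rows[sid] = vals
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=range(1, length + 1))
    with np.errstate(invalid="ignore"):
        means = df.mean(axis=0, skipna=True)
    return AlignmentProjection(alignment=alignment, values=df,
                               column_means=means,
                               binary_rows=set(binary_rows or ()),
                               annotations=annotations)


def projection_to_html(proj: AlignmentProjection, path) -> None:
    """Render the alignment with residues shaded white (0) to red (1)."""
    seqs = dict(proj.alignment)
    lines = ["<html><body><pre style='font-family:monospace'>"]
    for sid in proj.values.index:
        vals = proj.values.loc[sid].to_numpy(dtype=float)
        cells = []
        for c, v in zip(seqs[sid], vals):
            if np.isnan(v):
                cells.append(c)
            else:
                shade = int(255 * (1 - min(max(v, 0.0), 1.0)))
                cells.append(
                    f"<span style='background-color:rgb(255,{shade},{shade})'>{c}</span>")
        lines.append(f"{sid:<20s} " + "".join(cells))
    lines.append("</pre></body></html>")
    Path(path).write_text("\n".join(lines))
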