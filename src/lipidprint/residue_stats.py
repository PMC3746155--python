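"""Residue-type x lipid-segment interaction statistics across many systems.

Aggregates per-residue segment contact fractions from a set of profiles
into a table of amino-acid type against lipid segment (terminal head group,
phosphate, glycerol, tail), normalized by how often each residue type
occurs in the analyzed structures.  The normalization removes composition
bias: an abundant residue type does not dominate simply by being common.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactProfile
from .core_io import AnnotatedSystem, SEGMENTS

__all__ = ["SegmentInteractionTable", "segment_interaction_frequencies"]


@dataclass
class SegmentInteractionTable:
    """percentages: types x 4 segments, each segment column summing to 100
    (all-zero segments stay zero); normalized: occurrence-normalized raw
    scores before rescaling; occurrence: residue counts per type."""

    percentages: pd.DataFrame
    normalized: pd.DataFrame
    occurrence: pd.Series

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# percentage of occurrence-normalized contacts per lipid "
                     "segment (columns sum to 100)\n")
            out = self.percentages.copy()
            out["occurrence"] = self.occurrence
            out.to_csv(fh, sep="\t", index_label="residue_type")


def _occurrence(systems: Sequence[AnnotatedSystem]) -> pd.Series:
    counts: dict = {}
    for sys_i in systems:
        keys = sys_i.residue_keys()
        seen = set()
        for i in np.flatnonzero(sys_i.roles == "protein"):
            k = str(keys[i])
            if k in seen:
                continue
            seen.add(k)
            t = str(sys_i.residue_names[i])
            counts[t] = counts.get(t, 0) + 1
    return pd.Series(counts, dtype=float).sort_index()


def segment_interaction_frequencies(
        profiles: Sequence[ContactProfile],
        systems: Sequence[AnnotatedSystem],
        binary: bool = False) -> SegmentInteractionTable:
    """Occurrence-normalized percentage of residue-type contacts per segment.

    The raw score of (type, segment) sums the segment contact fraction over
    every residue of that type across all profiles (time-weighted); with
    ``binary=True`` each residue instead contributes 1 if it ever contacts
    the segment.  Raw scores are divided by the type's occurrence count in
    ``systems`` and rescaled so each segment column sums to 100.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) != len(systems):
        raise ValueError("profiles and systems must match one-to-one")
    occurrence = _occurrence(systems)

    raw = pd.DataFrame(0.0, index=occurrence.index, columns=list(SEGMENTS))
    for prof in profiles:
        df = prof.data
        for seg in SEGMENTS:
            vals = (df[seg] > 0).astype(float) if binary else df[seg]
            contrib = vals.groupby(df["resname"]).sum()
            missing = set(contrib.index) - set(occurrence.index)
            if missing:
                raise ValueError(
                    "residue type(s) in profiles but not in systems: "
                    + ", ".join(sorted(missing)))
            raw.loc[contrib.index, seg] += contrib.values

    normalized = raw.div(occurrence, axis=0)
    totals = normalized.sum(axis=0)
    percentages = normalized.copy()
    for seg in SEGMENTS:
        if totals[seg] > 0:
            percentages[seg] = 100.0 * normalized[seg] / totals[seg]
        else:
            percentages[seg] = 0.0
    return SegmentInteractionTable(percentages=percentages,
                                   normalized=normalized,
                                   occurrence=occurrence.astype(int))
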