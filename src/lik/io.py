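"""Readers and writers for the tabular formats the pipeline consumes.

Dialects follow the field's conventions: protein-group tables use the
MaxQuant ``proteinGroups.txt`` style ("LFQ intensity <sample>" columns, "+"
contaminant/decoy markers, 0 = not detected), gene sets use GMT, and
interaction edge lists use the STRING export style (two node columns plus a
confidence score on either a 0–1 or 0–1000 scale).

Identifiers are opaque strings; nothing here renames or maps them beyond
whitespace trimming.  Orthologue mapping is an explicit analysis step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "

_PG_META = {
    "Protein IDs": "protein_group_id",
    "Gene names": "gene_id",
    "Unique peptides": "unique_peptides",
    "Potential contaminant": "is_contaminant",
    "Reverse": "is_decoy",
}


@dataclass
class ProteinGroupTable:
    """Per-protein-group LFQ intensities across the designed samples.

    ``intensities`` is indexed by protein-group id with one nonnegative
    column per design sample; 0 encodes non-detection.  ``meta`` carries
    gene ids, unique-peptide counts and contaminant/decoy flags on the same
    index.
    """

    meta: pd.DataFrame          # gene_id, unique_peptides, is_contaminant, is_decoy
    intensities: pd.DataFrame   # one float column per sample_id

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensity tables disagree on protein ids")
        if self.meta.index.has_duplicates:
            raise FormatError("duplicate protein-group ids")
        if (self.intensities.to_numpy() < 0).any():
            raise FormatError("negative intensity")

    @property
    def protein_ids(self) -> pd.Index:
        return self.meta.index

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, keep: pd.Index | Iterable[str]) -> "ProteinGroupTable":
        keep = pd.Index(keep)
        return ProteinGroupTable(self.meta.loc[keep], self.intensities.loc[keep])

    def detected(self) -> pd.DataFrame:
        """Boolean detection matrix (intensity strictly positive)."""
        return self.intensities > 0

    def write(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.meta.index)
        out["Protein IDs"] = self.meta.index
        out["Gene names"] = self.meta["gene_id"]
        out["Unique peptides"] = self.meta["unique_peptides"]
        out["Potential contaminant"] = np.where(self.meta["is_contaminant"], "+", "")
        out["Reverse"] = np.where(self.meta["is_decoy"], "+", "")
        for c in self.intensities.columns:
            out[LFQ_PREFIX + c] = self.intensities[c]
        out.to_csv(path, sep="\t", index=False)


def parse_protein_groups(path: str | Path, design: ExperimentDesign) -> ProteinGroupTable:
    """Read a MaxQuant-style protein-groups TSV against a declared design.

    Raises :class:`FormatError` when a required column is absent and
    :class:`DesignError` when a designed sample has no intensity column.
    Missing intensity cells read as 0 (not detected).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("Protein IDs", "Unique peptides"):
        if col not in df.columns:
            raise FormatError(f"protein-groups table missing column {col!r}")

    meta = pd.DataFrame(index=pd.Index(df["Protein IDs"].astype(str).str.strip(),
                                       name="protein_group_id"))
    meta["gene_id"] = (
        df.get("Gene names", pd.Series("", index=df.index))
        .fillna("").astype(str).str.strip().to_numpy()
    )
    meta["unique_peptides"] = df["Unique peptides"].astype(int).to_numpy()
    for src, dst in (("Potential contaminant", "is_contaminant"),
                     ("Reverse", "is_decoy")):
        if src in df.columns:
            meta[dst] = (df[src].fillna("").astype(str).str.strip() == "+").to_numpy()
        else:
            meta[dst] = False

    cols = {}
    for s in design.sample_ids:
        for candidate in (LFQ_PREFIX + s, s):
            if candidate in df.columns:
                cols[s] = candidate
                break
        else:
            raise DesignError(f"no intensity column for designed sample {s!r}")
    inten = pd.DataFrame(
        {s: pd.to_numeric(df[c], errors="raise").fillna(0.0).to_numpy(dtype=float)
         for s, c in cols.items()},
        index=meta.index,
    )
    return ProteinGroupTable(meta, inten)


# --------------------------------------------------------------------------
# Gene sets (GMT)

@dataclass
class GeneSetCollection:
    """term_id -> (term_name, frozenset of member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def name(self, term: str) -> str:
        return self.sets[term][0]

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, (name, members) in self.sets.items():
                fh.write("\t".join([term, name, *sorted(members)]) + "\n")


def parse_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            term, name = fields[0].strip(), fields[1].strip()
            if term in sets:
                raise FormatError(f"GMT line {lineno}: duplicate term {term!r}")
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"GMT line {lineno}: term {term!r} has no members")
            sets[term] = (name, members)
    return GeneSetCollection(sets)


# --------------------------------------------------------------------------
# Interaction edge lists (STRING-export dialect)

def parse_edges(path: str | Path, score_scale: str = "unit") -> pd.DataFrame:
    """Read a 3-column (node, node, score) edge list into a tidy frame.

    ``score_scale`` is ``unit`` (scores already in [0,1]) or ``thousand``
    (STRING's integer 0–1000 combined score, divided by 1000).  Edges are
    undirected: duplicates collapse to one row keeping the maximum
    confidence; self-loops and zero-confidence edges are dropped.
    """
    if score_scale not in ("unit", "thousand"):
        raise ValueError(f"unknown score scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("edge list needs 3 columns: node, node, score")
    df = df.iloc[:, :3]
    df.columns = ["a", "b", "confidence"]
    df["a"] = df["a"].astype(str).str.strip()
    df["b"] = df["b"].astype(str).str.strip()
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
    hi = 1.0 if score_scale == "unit" else 1000.0
    if ((df["confidence"] < 0) | (df["confidence"] > hi)).any():
        raise FormatError(f"score outside declared {score_scale!r} scale [0, {hi}]")
    if score_scale == "thousand":
        df["confidence"] = df["confidence"] / 1000.0

    loops = df["a"] == df["b"]
    if loops.any():
        logger.warning("dropping %d self-loop edge row(s)", int(loops.sum()))
        df = df[~loops]
    df = df[df["confidence"] > 0]

    lo = df[["a", "b"]].min(axis=1)
    hi_node = df[["a", "b"]].max(axis=1)
    df = df.assign(a=lo, b=hi_node)
    df = (
        df.groupby(["a", "b"], as_index=False)["confidence"].max()
        .sort_values(["a", "b"], ignore_index=True)
    )
    return df


def write_edges(df: pd.DataFrame, path: str | Path) -> None:
    df[["a", "b", "confidence"]].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Per-residue disorder tracks

@dataclass
class DisorderTrack:
    """Per-residue disorder propensity scores in [0,1] for one protein."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise FormatError(f"track {self.protein_id!r} must have length >= 1")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise FormatError(f"track {self.protein_id!r} has scores outside [0,1]")

    def __len__(self) -> int:
        return self.scores.size


def parse_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    """Read a long-format TSV (protein_id, position, score) of tracks."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "position", "score"):
        if col not in df.columns:
            raise FormatError(f"disorder track table missing column {col!r}")
    tracks: dict[str, DisorderTrack] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        if not (grp["position"].to_numpy() == np.arange(1, len(grp) + 1)).all():
            raise FormatError(f"track {pid!r}: positions must run 1..L")
        tracks[str(pid)] = DisorderTrack(str(pid), grp["score"].to_numpy())
    return tracks


def write_disorder_tracks(tracks: Mapping[str, DisorderTrack], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "protein_id": t.protein_id,
            "position": np.arange(1, len(t) + 1),
            "score": t.scores,
        })
        for t in tracks.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_protein_list(path: str | Path) -> list[str]:
    """One protein id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
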