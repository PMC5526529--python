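"""Concatenated protein-coding-gene alignments (supermatrices).

A supermatrix is the classical phylogenomic data structure: the 13
mitochondrial protein-coding genes of each taxon, stop codons stripped,
concatenated in genome order, with a partition map recording which columns
belong to which gene and a per-column codon-position label.  Partition
intervals are half-open ``[start, end)`` internally; genome coordinates
elsewhere in the package stay 1-based inclusive and are converted only at
module boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Vertebrate mitochondrial stop codons (translation table 2).
MT_STOP_CODONS = {"TAA", "TAG", "AGA", "AGG"}

#: The paper-style 3-group partition preset over the 13 PCGs.
THREE_GROUP_SCHEME = {
    "group1": ["ATP6", "ATP8", "CYTB", "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5"],
    "group2": ["COX1", "COX2", "COX3"],
    "group3": ["ND6"],
}

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class GeneAlignment:
    """One per-gene alignment: equal-length rows over {A,C,G,T,-,N,IUPAC}."""

    gene_name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene_name}: {len(self.taxa)} taxa vs {len(self.rows)} rows")
        if len(self.taxa) < 2:
            raise ValueError(f"{self.gene_name}: need >= 2 taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_name}: unequal row lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class Supermatrix:
    """Concatenated alignment with partition map and codon-position labels."""

    taxa: list[str]
    rows: list[str]
    #: gene -> (start, end) half-open column interval, in concatenation order
    partition_map: dict[str, tuple[int, int]]
    #: per-column codon position label in {1, 2, 3}
    codon_positions: np.ndarray = field(default=None)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("unequal row lengths")
        width = lengths.pop()
        intervals = sorted(self.partition_map.values())
        pos = 0
        for s, e in intervals:
            if s != pos:
                raise ValueError("partition intervals do not tile the matrix")
            pos = e
        if pos != width:
            raise ValueError(f"partitions cover {pos} columns, matrix has {width}")
        if self.codon_positions is None:
            self.codon_positions = _default_codon_labels(self.partition_map, width)
        self.codon_positions = np.asarray(self.codon_positions, dtype=np.int8)
        if len(self.codon_positions) != width:
            raise ValueError("codon label vector length mismatch")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def as_array(self) -> np.ndarray:
        """Character matrix as an (n_taxa, width) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def columns(self, idx) -> "Supermatrix":
        """Subset columns by an index array; partition map is re-derived."""
        idx = np.asarray(idx)
        arr = np.array([list(r) for r in self.rows], dtype="U1")[:, idx]
        new_rows = ["".join(row) for row in arr]
        new_map = {}
        pos = 0
        for gene, (s, e) in sorted(self.partition_map.items(), key=lambda kv: kv[1]):
            kept = int(((idx >= s) & (idx < e)).sum())
            new_map[gene] = (pos, pos + kept)
            pos += kept
        return Supermatrix(
            taxa=list(self.taxa), rows=new_rows, partition_map=new_map,
            codon_positions=self.codon_positions[idx],
        )

    def gene_slice(self, gene: str) -> GeneAlignment:
        s, e = self.partition_map[gene]
        return GeneAlignment(gene, list(self.taxa), [r[s:e] for r in self.rows])

    def exclude_gene(self, gene: str) -> "Supermatrix":
        s, e = self.partition_map[gene]
        keep = np.r_[0:s, e:self.width]
        sub = self.columns(keep)
        del sub.partition_map[gene]
        return sub

    def gene_order(self) -> list[str]:
        return [g for g, _ in sorted(self.partition_map.items(), key=lambda kv: kv[1])]


def _default_codon_labels(partition_map, width) -> np.ndarray:
    labels = np.zeros(width, dtype=np.int8)
    for _, (s, e) in partition_map.items():
        labels[s:e] = (np.arange(e - s) % 3) + 1
    return labels


def strip_stop_codon(cds: str, code: int = 2) -> tuple[str, dict]:
    """Remove the trailing stop codon of a CDS (vertebrate mitochondrial code).

    A trailing complete stop (TAA/TAG/AGA/AGG) is removed; a length not
    divisible by 3 is trimmed back to a codon boundary and flagged, which is
    how a +1 frameshift insertion (WEC ND3) manifests here.

    Returns ``(sequence, flags)`` with flags ``incomplete_terminal``,
    ``stop_removed`` and ``frameshift_suspect``.
    """
    if len(cds) < 6:
        raise ValueError("CDS shorter than 6 nt")
    seq = cds.upper()
    flags = {"incomplete_terminal": False, "stop_removed": False,
             "frameshift_suspect": False}
    rem = len(seq) % 3
    if rem:
        # A complete trailing stop in the shifted frame signals an internal
        # +1/+2 frameshift rather than a partially sequenced terminator.
        if seq[-3:] in MT_STOP_CODONS:
            flags["frameshift_suspect"] = True
        seq = seq[:len(seq) - rem]
        flags["incomplete_terminal"] = True
    if len(seq) >= 3 and seq[-3:] in MT_STOP_CODONS:
        seq = seq[:-3]
        flags["stop_removed"] = True
    return seq, flags


def concatenate(genes: list[GeneAlignment], gene_order: list[str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.

    All genes must cover an identical taxon set; rows are ordered by the
    first gene's taxon order, columns by ``gene_order`` (default: the input
    list order).
    """
    if not genes:
        raise ValueError("no gene alignments supplied")
    by_name = {g.gene_name: g for g in genes}
    if gene_order is None:
        gene_order = [g.gene_name for g in genes]
    missing = [n for n in gene_order if n not in by_name]
    if missing:
        raise ValueError(f"gene_order names absent from inputs: {missing}")
    taxa = list(genes[0].taxa)
    ref = set(taxa)
    for g in genes:
        if set(g.taxa) != ref:
            raise ValueError(
                f"taxon set mismatch in {g.gene_name}: "
                f"missing={sorted(ref - set(g.taxa))} extra={sorted(set(g.taxa) - ref)}"
            )
    parts = {}
    pos = 0
    rows = {t: [] for t in taxa}
    for name in gene_order:
        g = by_name[name]
        parts[name] = (pos, pos + g.length)
        pos += g.length
        lookup = dict(zip(g.taxa, g.rows))
        for t in taxa:
            rows[t].append(lookup[t])
    return Supermatrix(taxa=taxa, rows=["".join(rows[t]) for t in taxa],
                       partition_map=parts)


def remove_incomplete_columns(sm: Supermatrix) -> Supermatrix:
    """Drop every column containing a gap or ambiguous base in any taxon."""
    arr = np.array([list(r) for r in sm.rows], dtype="U1")
    ok = np.isin(arr, list("ACGT")).all(axis=0)
    return sm.columns(np.flatnonzero(ok))


# ---------------------------------------------------------------- file I/O

def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP writer."""
    with open(path, "w") as fh:
        fh.write(f"{sm.n_taxa} {sm.width}\n")
        for t, r in zip(sm.taxa, sm.rows):
            fh.write(f"{t}  {r}\n")


def read_phylip(path: str | Path) -> tuple[list[str], list[str]]:
    """Relaxed PHYLIP reader -> (taxa, rows); no partition info in this format."""
    with open(path) as fh:
        header = fh.readline().split()
        n, width = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip())
    if len(taxa) != n or any(len(r) != width for r in rows):
        raise ValueError(f"{path}: header {n}x{width} does not match contents")
    return taxa, rows


def write_partitions_raxml(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file: ``DNA, name = start-end`` (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in sm.gene_order():
            s, e = sm.partition_map[gene]
            fh.write(f"DNA, {gene} = {s + 1}-{e}\n")


def write_partitions_json(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({g: list(iv) for g, iv in sm.partition_map.items()}, fh, indent=1)
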