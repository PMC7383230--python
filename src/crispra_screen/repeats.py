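"""Repeat-family quantification from multi-mapping reads.

Per-family references are built by stitching all instance sequences of a
family with 'NNNNN' separators into one family genome. Reads are mapped
with a windowed edit-distance scan (exact 12-mer seeds, verified by
banded edit distance <= 2) instead of an external aligner; the counting
semantics — per-family mapping, exclusion of cross-family multimappers,
UMI collapsing to molecules — are preserved. A junction-crossing
alignment must traverse five N characters and therefore always exceeds
the edit budget, so windows spanning instance boundaries are excluded by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

SEPARATOR = "NNNNN"
UNMAPPED = "UNMAPPED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class RepeatFamilyRef:
    family_name: str
    instance_sequences: list
    stitched_genome: str = field(init=False)

    def __post_init__(self):
        if not self.instance_sequences:
            raise ValueError(f"repeat family {self.family_name} has no instances")
        self.stitched_genome = SEPARATOR.join(self.instance_sequences)


def build_repeat_reference(families) -> list:
    """families: iterable of (name, [instance sequences])."""
    return [RepeatFamilyRef(name, list(instances)) for name, instances in families]


class RepeatMapper:
    """Seed-and-verify mapper of reads onto stitched family genomes."""

    def __init__(self, references, max_edits: int = 2, seed_length: int = 12):
        self.references = list(references)
        if not self.references:
            raise ValueError("no repeat references")
        self.max_edits = max_edits
        self.seed_length = seed_length
        self._index: dict = {}
        for fi, ref in enumerate(self.references):
            g = ref.stitched_genome
            for pos in range(len(g) - seed_length + 1):
                kmer = g[pos:pos + seed_length]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((fi, pos))

    def _map_to_family(self, read: str, fi: int, positions) -> bool:
        genome = self.references[fi].stitched_genome
        k = self.max_edits
        for seed_off, gpos in positions:
            lo = max(0, gpos - seed_off - k)
            hi = min(len(genome), gpos - seed_off + len(read) + k)
            window = genome[lo:hi]
            res = edlib.align(read, window, mode="HW", task="locations", k=k)
            if res["editDistance"] == -1:
                continue
            # alignments whose genome window touches the NNNNN separator
            # are excluded: reads must map within a single instance
            for start, end in res["locations"]:
                if start is None:
                    start = max(end - len(read) + 1, 0)
                if "N" not in window[start:end + 1]:
                    return True
        return False

    def map_read(self, sequence: str) -> str:
        """Family name, AMBIGUOUS (>= 2 families match) or UNMAPPED."""
        read = str(sequence)
        L = self.seed_length
        if len(read) < L:
            return UNMAPPED
        # seeds at offsets spaced so that <= max_edits errors cannot hit all
        n_seeds = self.max_edits + 1
        offsets = sorted({int(round(i * (len(read) - L) / max(n_seeds - 1, 1)))
                         for i in range(n_seeds)})
        cand: dict = {}
        for off in offsets:
            for fi, gpos in self._index.get(read[off:off + L], ()):
                cand.setdefault(fi, []).append((off, gpos))
        matched = [fi for fi, positions in cand.items()
                   if self._map_to_family(read, fi, positions)]
        if not matched:
            return UNMAPPED
        if len(matched) > 1:
            return AMBIGUOUS
        return self.references[matched[0]].family_name


def map_read_to_family(read, references, max_edits: int = 2,
                       mapper: RepeatMapper | None = None) -> str:
    if mapper is None:
        mapper = RepeatMapper(references, max_edits=max_edits)
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    return mapper.map_read(seq)


def map_reads(reads, references, max_edits: int = 2) -> pd.DataFrame:
    """Map a read set; returns per-read table with columns cell_barcode,
    umi, family (family name, UNMAPPED or AMBIGUOUS)."""
    mapper = RepeatMapper(references, max_edits=max_edits)
    rows = []
    for r in reads:
        rows.append((r.cell_barcode, r.umi, mapper.map_read(r.sequence)))
    return pd.DataFrame(rows, columns=["cell_barcode", "umi", "family"])


@dataclass
class RepeatCounts:
    """UMI-collapsed molecule counts per cell and family."""

    molecules: pd.DataFrame  # cells x families
    family_read_totals: pd.Series  # mapped reads per family
    n_unmapped: int = 0
    n_ambiguous: int = 0

    @property
    def families(self):
        return list(self.molecules.columns)


def collapse_umis(mapped: pd.DataFrame, cell_barcodes=None) -> RepeatCounts:
    """Collapse reads sharing (cell barcode, UMI, family) into molecules.

    ``mapped`` is the output of :func:`map_reads`; UNMAPPED/AMBIGUOUS
    reads are tallied but excluded from counts. ``cell_barcodes``
    optionally fixes the row universe (cells without reads get zeros).
    """
    is_unmapped = mapped["family"] == UNMAPPED
    is_ambiguous = mapped["family"] == AMBIGUOUS
    ok = mapped.loc[~(is_unmapped | is_ambiguous)]
    family_reads = ok.groupby("family").size()
    molecules = ok.drop_duplicates(["cell_barcode", "umi", "family"])
    table = pd.crosstab(molecules["cell_barcode"], molecules["family"])
    table.index.name = "barcode"
    if cell_barcodes is not None:
        table = table.reindex(pd.Index(cell_barcodes, name="barcode"), fill_value=0)
    families = sorted(set(family_reads.index) | set(table.columns))
    table = table.reindex(columns=families, fill_value=0).astype(np.int64)
    return RepeatCounts(
        molecules=table,
        family_read_totals=family_reads.reindex(families, fill_value=0).astype(np.int64),
        n_unmapped=int(is_unmapped.sum()),
        n_ambiguous=int(is_ambiguous.sum()),
    )


def filter_families(counts: RepeatCounts, min_total_reads: int = 1000) -> RepeatCounts:
    """Drop families with fewer than ``min_total_reads`` mapped reads
    (removes inefficiently mapping families from downstream analysis)."""
    keep = counts.family_read_totals[counts.family_read_totals >= min_total_reads].index
    return RepeatCounts(
        molecules=counts.molecules[list(keep)],
        family_read_totals=counts.family_read_totals[list(keep)],
        n_unmapped=counts.n_unmapped,
        n_ambiguous=counts.n_ambiguous,
    )
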