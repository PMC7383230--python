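"""Assignment of sgRNAs to cells from amplicon reads.

Matching is two-tier. Tier 1 takes exact protospacer matches (read bases
24-43, 1-based) against the whitelist. Tier 2 rescues reads whose
extracted protospacer is within Levenshtein distance 1-2 of exactly one
guide, provided the read's flanking 23-nt segments each match the vector
arms with at most 4 edits. Because the whitelist enforces a minimum
pairwise distance of 4, a corrected read can match at most one guide
(triangle inequality), so correction is unambiguous by construction.

Per-cell calls use a binomial-confidence rule: a cell is uniquely
assigned when the modal guide holds a fraction p-hat > 0.9 of the cell's
assigned reads and the binomial standard error evaluated at the 0.9
threshold, sqrt(0.9 * 0.1 / n), is <= 0.1 — equivalently n >= 9 reads.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import edlib
import numpy as np
import pandas as pd

from .guides import GuideLibrary, validate_library

UNASSIGNED = "UNASSIGNED"

# 1-based inclusive read layout (mirrors the amplicon design)
PROTO_START_1BASED = 24
PROTO_END_1BASED = 43
CONTEXT_LEN = 23
FULL_READ_LEN = 66

SUPPORT_FRACTION_THRESHOLD = 0.9
SE_THRESHOLD = 0.1
MIN_SUPPORT_READS_TWO = 2


class MatchTier(str, Enum):
    EXACT = "exact"
    CORRECTED = "corrected"
    NONE = "none"


class CellCategory(str, Enum):
    NONE = "none"
    UNIQUE = "unique"
    TWO = "two"
    MULTIPLE = "multiple"


@dataclass
class ReadAssignment:
    cell_barcode: str
    umi: str
    guide_id: str  # UNASSIGNED when no guide matched
    tier: MatchTier
    reason: str = ""


@dataclass
class CellAssignment:
    cell_barcode: str
    category: CellCategory
    assigned_guide: str  # "" unless category is unique
    support_reads: int
    total_reads: int
    support_fraction: float


def extract_protospacer(sequence: str) -> str:
    """Bases 24-43 (1-based, inclusive) of the read: the candidate
    protospacer. Raises on reads shorter than 43 nt."""
    if len(sequence) < PROTO_END_1BASED:
        raise ValueError(f"read of length {len(sequence)} has no bases {PROTO_START_1BASED}-{PROTO_END_1BASED}")
    return sequence[PROTO_START_1BASED - 1:PROTO_END_1BASED]


class GuideMatcher:
    """Two-tier read matcher against a validated guide whitelist.

    Tier-2 candidate generation uses a pigeonhole filter: each
    protospacer is split into three pieces; any guide within edit
    distance <= 2 of an extracted 20-mer must contain at least one piece
    verbatim as a substring of that 20-mer. Candidates are then verified
    by full Levenshtein distance.
    """

    def __init__(self, library: GuideLibrary, max_edits: int = 2,
                 max_context_edits: int = 4, require_valid_library: bool = True):
        self.library = library
        self.max_edits = max_edits
        self.max_context_edits = max_context_edits
        report = validate_library(library)
        self.library_valid = report.is_valid
        if require_valid_library and not self.library_valid:
            # correction tier is refused on ambiguous whitelists
            self.correction_enabled = False
        else:
            self.correction_enabled = True
        protos = library.guides["protospacer"].to_numpy()
        ids = library.guides["guide_id"].to_numpy()
        self._exact = dict(zip(protos, ids))
        self._protos = protos
        self._ids = ids
        # pigeonhole piece index
        self._piece_index: dict = {}
        self._piece_lengths = set()
        for gi, p in enumerate(protos):
            L = len(p)
            cuts = [0, L // 3, 2 * L // 3, L]
            for a, b in zip(cuts[:-1], cuts[1:]):
                piece = p[a:b]
                self._piece_lengths.add(len(piece))
                self._piece_index.setdefault(piece, set()).add(gi)

    def _candidates(self, proto: str):
        cand: set = set()
        for L in self._piece_lengths:
            for start in range(0, len(proto) - L + 1):
                hit = self._piece_index.get(proto[start:start + L])
                if hit:
                    cand |= hit
        return cand

    def match(self, sequence: str) -> tuple:
        """Return (guide_id or UNASSIGNED, MatchTier, reason)."""
        if len(sequence) < PROTO_END_1BASED:
            return UNASSIGNED, MatchTier.NONE, "read shorter than 43 nt"
        proto = extract_protospacer(sequence)
        hit = self._exact.get(proto)
        if hit is not None:
            return hit, MatchTier.EXACT, ""
        if not self.correction_enabled:
            return UNASSIGNED, MatchTier.NONE, "correction disabled (invalid library)"
        best_d, best_gi, n_best = self.max_edits + 1, -1, 0
        for gi in self._candidates(proto):
            d = edlib.align(proto, self._protos[gi], mode="NW", task="distance",
                            k=self.max_edits)["editDistance"]
            if d == -1:
                continue
            if d < best_d:
                best_d, best_gi, n_best = d, gi, 1
            elif d == best_d:
                n_best += 1
        if best_gi < 0:
            return UNASSIGNED, MatchTier.NONE, "no guide within correction radius"
        if n_best > 1:
            return UNASSIGNED, MatchTier.NONE, "ambiguous correction"
        if len(sequence) < FULL_READ_LEN:
            return UNASSIGNED, MatchTier.NONE, "read too short for context check"
        up = sequence[:CONTEXT_LEN]
        down = sequence[PROTO_END_1BASED:PROTO_END_1BASED + CONTEXT_LEN]
        for observed, expected in ((up, self.library.upstream_context),
                                   (down, self.library.downstream_context)):
            d = edlib.align(observed, expected, mode="NW", task="distance",
                            k=self.max_context_edits)["editDistance"]
            if d == -1:
                return UNASSIGNED, MatchTier.NONE, "vector context mismatch"
        return self._ids[best_gi], MatchTier.CORRECTED, ""


def match_read(read, library: GuideLibrary, matcher: GuideMatcher | None = None) -> ReadAssignment:
    """Assign a single amplicon read to a guide (or UNASSIGNED)."""
    if matcher is None:
        matcher = GuideMatcher(library)
    guide, tier, reason = matcher.match(read.sequence)
    return ReadAssignment(read.cell_barcode, read.umi, guide, tier, reason)


def match_reads(reads, library: GuideLibrary, matcher: GuideMatcher | None = None) -> pd.DataFrame:
    """Vectorised assignment of many reads; returns a per-read table with
    columns cell_barcode, umi, guide_id, tier."""
    if matcher is None:
        matcher = GuideMatcher(library)
    if hasattr(reads, "cell_barcodes"):
        barcodes = np.asarray(reads.cell_barcodes)
        umis = np.asarray(reads.umis)
        seqs = np.asarray(reads.sequences, dtype=str)
    else:
        rows = list(reads)
        barcodes = np.array([r.cell_barcode for r in rows])
        umis = np.array([r.umi for r in rows])
        seqs = np.array([r.sequence for r in rows])

    guide = np.full(len(seqs), UNASSIGNED, dtype=object)
    tier = np.full(len(seqs), MatchTier.NONE.value, dtype=object)
    lengths = np.char.str_len(seqs.astype(str))
    long_enough = lengths >= PROTO_END_1BASED
    if long_enough.all() and lengths.min() == lengths.max():
        # fixed-length reads: slice the protospacer column block in bulk
        L = int(lengths[0])
        byte_view = seqs.astype(f"S{L}").view("S1").reshape(len(seqs), L)
        protos = (
            byte_view[:, PROTO_START_1BASED - 1:PROTO_END_1BASED]
            .copy()
            .view(f"S{PROTO_END_1BASED - PROTO_START_1BASED + 1}")
            .ravel()
            .astype("U")
        )
    else:
        protos = np.array([s[PROTO_START_1BASED - 1:PROTO_END_1BASED] if ok else ""
                           for s, ok in zip(seqs, long_enough)], dtype=object)
    exact = pd.Series(protos).map(matcher._exact)
    hit_mask = exact.notna().to_numpy()
    guide[hit_mask] = exact[hit_mask].to_numpy()
    tier[hit_mask] = MatchTier.EXACT.value
    for i in np.flatnonzero(~hit_mask):
        g, t, _ = matcher.match(str(seqs[i]))
        guide[i] = g
        tier[i] = t.value
    return pd.DataFrame(
        {"cell_barcode": barcodes, "umi": umis, "guide_id": guide, "tier": tier}
    )


def assign_cell(read_assignments) -> CellAssignment:
    """Call the sgRNA of one cell barcode from its read assignments.

    UNASSIGNED reads are excluded from the denominator. Unique iff the
    modal guide's support fraction exceeds 0.9 and the binomial standard
    error at the threshold, sqrt(0.9*0.1/n), is <= 0.1 (n >= 9). With no
    unique call, two/multiple categories count guides with >= 2
    supporting reads.
    """
    rows = list(read_assignments)
    if not rows:
        raise ValueError("no reads for barcode")
    barcode = rows[0].cell_barcode if hasattr(rows[0], "cell_barcode") else rows[0][0]
    guides = [r.guide_id if hasattr(r, "guide_id") else r[1] for r in rows]
    counts = Counter(g for g in guides if g != UNASSIGNED)
    return _call_from_counts(barcode, counts)


def _call_from_counts(barcode: str, counts: Counter) -> CellAssignment:
    n = sum(counts.values())
    if n == 0:
        return CellAssignment(barcode, CellCategory.NONE, "", 0, 0, 0.0)
    modal_guide, k = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    phat = k / n
    se_ok = np.sqrt(SUPPORT_FRACTION_THRESHOLD * (1 - SUPPORT_FRACTION_THRESHOLD) / n) <= SE_THRESHOLD
    if phat > SUPPORT_FRACTION_THRESHOLD and se_ok:
        return CellAssignment(barcode, CellCategory.UNIQUE, modal_guide, k, n, phat)
    supported = sum(1 for c in counts.values() if c >= MIN_SUPPORT_READS_TWO)
    if supported == 2:
        return CellAssignment(barcode, CellCategory.TWO, "", k, n, phat)
    if supported >= 3:
        return CellAssignment(barcode, CellCategory.MULTIPLE, "", k, n, phat)
    return CellAssignment(barcode, CellCategory.NONE, "", k, n, phat)


def assign_cells(read_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell sgRNA calls from a per-read assignment table.

    Returns a frame indexed by barcode with columns category,
    assigned_guide, support_reads, total_reads, support_fraction.
    """
    assigned = read_table.loc[read_table["guide_id"] != UNASSIGNED]
    per = (
        assigned.groupby(["cell_barcode", "guide_id"], sort=False)
        .size()
        .rename("reads")
        .reset_index()
    )
    # modal guide with the same tie-break as assign_cell: highest count,
    # then lexicographically larger guide id
    per = per.sort_values(["cell_barcode", "reads", "guide_id"])
    modal = per.groupby("cell_barcode", sort=False).last()
    agg = per.groupby("cell_barcode", sort=False)["reads"].agg(n="sum")
    agg["k"] = modal["reads"]
    agg["modal_guide"] = modal["guide_id"]
    agg["n_supported"] = (
        per.loc[per["reads"] >= MIN_SUPPORT_READS_TWO]
        .groupby("cell_barcode", sort=False)
        .size()
        .reindex(agg.index, fill_value=0)
    )
    phat = agg["k"] / agg["n"]
    se_ok = np.sqrt(
        SUPPORT_FRACTION_THRESHOLD * (1 - SUPPORT_FRACTION_THRESHOLD) / agg["n"]
    ) <= SE_THRESHOLD
    unique = (phat > SUPPORT_FRACTION_THRESHOLD) & se_ok
    category = np.where(
        unique, CellCategory.UNIQUE.value,
        np.where(agg["n_supported"] == 2, CellCategory.TWO.value,
                 np.where(agg["n_supported"] >= 3, CellCategory.MULTIPLE.value,
                          CellCategory.NONE.value)),
    )
    df = pd.DataFrame(
        {
            "category": category,
            "assigned_guide": np.where(unique, agg["modal_guide"], ""),
            "support_reads": agg["k"].to_numpy(),
            "total_reads": agg["n"].to_numpy(),
            "support_fraction": phat.to_numpy(),
        },
        index=agg.index.rename("barcode"),
    )
    # barcodes whose every read was unassigned still appear, as category none
    missing = pd.Index(read_table["cell_barcode"].unique()).difference(df.index)
    if len(missing):
        df = pd.concat([
            df,
            pd.DataFrame(
                {
                    "category": CellCategory.NONE.value,
                    "assigned_guide": "",
                    "support_reads": 0,
                    "total_reads": 0,
                    "support_fraction": 0.0,
                },
                index=missing.rename("barcode"),
            ),
        ])
    return df.sort_index()


def match_barcodes(assignments: pd.DataFrame, expression_barcodes) -> pd.DataFrame:
    """Keep only cell assignments whose barcode appears in the expression
    matrix (the QC-passed count data)."""
    keep = assignments.index.isin(set(expression_barcodes))
    return assignments.loc[keep]


def assignment_summary(assignments: pd.DataFrame) -> dict:
    """Category counts and percentages, mirroring the per-replicate
    assignment table layout."""
    total = len(assignments)
    counts = assignments["category"].value_counts().to_dict()
    summary = {"total_barcodes": total, "categories": {}}
    for cat in CellCategory:
        n = int(counts.get(cat.value, 0))
        summary["categories"][cat.value] = {
            "count": n,
            "percentage": round(100.0 * n / total, 2) if total else 0.0,
        }
    return summary


def write_summary_json(assignments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(assignment_summary(assignments), fh, indent=2)
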