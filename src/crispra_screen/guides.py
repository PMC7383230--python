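"""Guide library container and whitelist validation.

A guide library is the sgRNA whitelist of the screen: one 20-nt
protospacer per guide, its target gene (or none for non-targeting
controls), and the fixed 23-nt vector arms that flank the protospacer in
amplicon reads. Error-corrected read matching is only safe when every
pair of protospacers is at Levenshtein distance >= 4, so correction
within distance 2 can never reach two different guides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .config import DOWNSTREAM_CONTEXT, UPSTREAM_CONTEXT


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions, deletions)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass
class GuideLibrary:
    guides: pd.DataFrame  # columns: guide_id, protospacer, target_gene, is_targeting
    upstream_context: str = UPSTREAM_CONTEXT
    downstream_context: str = DOWNSTREAM_CONTEXT

    def __post_init__(self):
        required = {"guide_id", "protospacer", "target_gene", "is_targeting"}
        missing = required - set(self.guides.columns)
        if missing:
            raise ValueError(f"guide table missing columns: {sorted(missing)}")
        if self.guides["guide_id"].duplicated().any():
            raise ValueError("duplicate guide ids")
        if len(self.upstream_context) != 23 or len(self.downstream_context) != 23:
            raise ValueError("vector contexts must be exactly 23 nt")

    def __len__(self) -> int:
        return len(self.guides)

    @property
    def protospacers(self) -> pd.Series:
        return self.guides.set_index("guide_id")["protospacer"]

    @property
    def targeting_ids(self) -> list:
        return self.guides.loc[self.guides["is_targeting"], "guide_id"].tolist()

    @property
    def nontargeting_ids(self) -> list:
        return self.guides.loc[~self.guides["is_targeting"], "guide_id"].tolist()

    def target_of(self, guide_id: str) -> str:
        row = self.guides.loc[self.guides["guide_id"] == guide_id]
        if row.empty:
            raise KeyError(guide_id)
        return row["target_gene"].iloc[0]

    def to_tsv(self, path) -> None:
        out = self.guides.copy()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, upstream_context=UPSTREAM_CONTEXT,
                 downstream_context=DOWNSTREAM_CONTEXT) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t")
        df["is_targeting"] = df["is_targeting"].astype(bool)
        df["target_gene"] = df["target_gene"].fillna("")
        return cls(df, upstream_context, downstream_context)


@dataclass
class LibraryValidation:
    """Report of guide pairs closer than the minimum whitelist distance."""

    min_distance: int
    invalid_pairs: list = field(default_factory=list)  # (id_a, id_b, distance)

    @property
    def is_valid(self) -> bool:
        return not self.invalid_pairs


def validate_library(library: GuideLibrary, min_distance: int = 4) -> LibraryValidation:
    """Report all guide pairs with pairwise Levenshtein distance below
    ``min_distance``. The library is valid iff no such pair exists;
    error-corrected matching must be refused on invalid libraries."""
    if len(library) == 0:
        raise ValueError("empty guide library")
    ids = library.guides["guide_id"].to_numpy()
    seqs = library.guides["protospacer"].to_numpy()
    report = LibraryValidation(min_distance=min_distance)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            # cheap lower bound: length difference
            if abs(len(seqs[i]) - len(seqs[j])) >= min_distance:
                continue
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance",
                            k=min_distance - 1)["editDistance"]
            if d != -1:
                report.invalid_pairs.append((ids[i], ids[j], d))
    return report


def min_pairwise_distance(library: GuideLibrary) -> int:
    seqs = library.guides["protospacer"].tolist()
    best = min(len(s) for s in seqs)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance",
                            k=best - 1)["editDistance"]
            if d != -1:
                best = d
                if best == 0:
                    return 0
    return best
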