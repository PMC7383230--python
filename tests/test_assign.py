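"""sgRNA-to-cell assignment: read matching tiers, the binomial
confidence rule, and agreement with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from crispra_screen.assign import (
    UNASSIGNED,
    CellCategory,
    GuideMatcher,
    MatchTier,
    ReadAssignment,
    assign_cell,
    assign_cells,
    extract_protospacer,
    match_barcodes,
    match_read,
    match_reads,
)
from crispra_screen.guides import GuideLibrary, validate_library
from crispra_screen.io import SequencedRead
from crispra_screen.simulate import generate_amplicon_reads, generate_cells, generate_library

from _oracles import brute_force_cell_call, brute_force_match, dp_levenshtein
from conftest import small_config


@pytest.fixture(scope="module")
def library():
    return generate_library(small_config(n_target_genes=10, n_nontargeting=5, seed=17))


def _read(library, proto, up=None, down=None):
    up = library.upstream_context if up is None else up
    down = library.downstream_context if down is None else down
    return SequencedRead("A" * 16, "C" * 10, up + proto + down)


def _mutate(seq, positions, rng):
    out = list(seq)
    for i in positions:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestExtract:
    def test_positions_24_to_43(self):
        seq = "A" * 23 + "ACGTACGTACGTACGTACGT" + "T" * 23
        assert extract_protospacer(seq) == "ACGTACGTACGTACGTACGT"

    def test_length_42_raises(self):
        with pytest.raises(ValueError):
            extract_protospacer("A" * 42)

    def test_synthetic_read_round_trip(self, library):
        cfg = small_config(base_error_rate=0.0, contamination_rate=0.0, doublet_rate=0.0,
                           n_target_genes=10, n_nontargeting=5, seed=17)
        rng = np.random.default_rng(17)
        _, truth = generate_cells(cfg, library, rng)
        reads = generate_amplicon_reads(cfg, truth, library, rng)
        protos = library.guides.set_index("guide_id")["protospacer"]
        for r in list(reads)[:100]:
            assert extract_protospacer(r.sequence) == protos[truth.cell_guides.loc[r.cell_barcode, "guide_1"]]


class TestValidateLibrary:
    def test_one_substitution_pair_reported(self):
        g = pd.DataFrame({
            "guide_id": ["a", "b"],
            "protospacer": ["ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGA"],
            "target_gene": ["x", "y"],
            "is_targeting": [True, True],
        })
        report = validate_library(GuideLibrary(g))
        assert not report.is_valid
        assert report.invalid_pairs[0][2] == 1

    def test_duplicate_protospacer_distance_zero(self):
        g = pd.DataFrame({
            "guide_id": ["a", "b"],
            "protospacer": ["ACGTACGTACGTACGTACGT"] * 2,
            "target_gene": ["x", "y"],
            "is_targeting": [True, True],
        })
        report = validate_library(GuideLibrary(g))
        assert report.invalid_pairs[0][2] == 0

    def test_generated_library_valid(self, library):
        assert validate_library(library).is_valid


class TestMatchRead:
    def test_exact_match_ignores_contexts(self, library):
        proto = library.guides["protospacer"].iloc[0]
        read = _read(library, proto, up="G" * 23, down="G" * 23)
        ra = match_read(read, library)
        assert ra.guide_id == library.guides["guide_id"].iloc[0]
        assert ra.tier == MatchTier.EXACT

    def test_one_substitution_corrected(self, library, rng):
        proto = library.guides["protospacer"].iloc[3]
        mutated = _mutate(proto, [7], rng)
        # brute force: unique nearest guide at distance 1
        dists = sorted(dp_levenshtein(mutated, p) for p in library.guides["protospacer"])
        assert dists[0] == 1 and dists[1] > 2
        ra = match_read(_read(library, mutated), library)
        assert ra.guide_id == library.guides["guide_id"].iloc[3]
        assert ra.tier == MatchTier.CORRECTED

    def test_three_edits_unassigned(self, library, rng):
        proto = library.guides["protospacer"].iloc[5]
        mutated = _mutate(proto, [2, 9, 16], rng)
        assert min(dp_levenshtein(mutated, p) for p in library.guides["protospacer"]) == 3
        ra = match_read(_read(library, mutated), library)
        assert ra.guide_id == UNASSIGNED

    def test_corrected_requires_contexts(self, library, rng):
        proto = _mutate(library.guides["protospacer"].iloc[2], [4], rng)
        bad_up = "G" * 23  # far beyond 4 edits from the vector arm
        ra = match_read(_read(library, proto, up=bad_up), library)
        assert ra.guide_id == UNASSIGNED

    def test_exact_precedence_over_correction(self, library):
        # an exact protospacer is never re-routed through the corrected tier
        for proto, gid in zip(library.guides["protospacer"], library.guides["guide_id"]):
            ra = match_read(_read(library, proto), library)
            assert (ra.guide_id, ra.tier) == (gid, MatchTier.EXACT)

    def test_agreement_with_brute_force_on_random_reads(self, library, rng):
        """1,000 mixed reads: exact, lightly mutated, heavily mutated and
        fully random; two-tier matcher must agree with the exhaustive
        Levenshtein oracle read by read."""
        matcher = GuideMatcher(library)
        protos = library.guides["protospacer"].tolist()
        reads = []
        for i in range(1000):
            kind = i % 4
            if kind == 0:
                p = protos[int(rng.integers(len(protos)))]
            elif kind in (1, 2):
                base = protos[int(rng.integers(len(protos)))]
                k = int(rng.integers(1, 4))
                pos = rng.choice(20, size=k, replace=False)
                p = _mutate(base, pos, rng)
            else:
                p = "".join(rng.choice(list("ACGT"), size=20))
            up = library.upstream_context
            if rng.random() < 0.2:
                up = _mutate(up, rng.choice(23, size=int(rng.integers(1, 7)), replace=False), rng)
            reads.append(up + p + library.downstream_context)
        for seq in reads:
            expected_guide, expected_tier = brute_force_match(seq, library)
            got_guide, got_tier, _ = matcher.match(seq)
            if expected_guide is None:
                assert got_guide == UNASSIGNED
            else:
                assert got_guide == expected_guide
                assert got_tier.value == expected_tier

    def test_correction_radius_cannot_be_ambiguous(self, library):
        # min whitelist distance >= 4 and radius <= 2: at most one guide
        # can ever be within the correction radius of any 20-mer
        protos = library.guides["protospacer"].tolist()
        for i in range(len(protos)):
            for j in range(i + 1, len(protos)):
                assert dp_levenshtein(protos[i], protos[j]) >= 4


class TestAssignCell:
    def _reads(self, counts):
        out = []
        for gid, k in counts.items():
            out += [ReadAssignment("CB", "U", gid, MatchTier.EXACT)] * k
        return out

    def test_nine_reads_single_guide_unique(self):
        call = assign_cell(self._reads({"g1": 9}))
        assert call.category == CellCategory.UNIQUE
        assert call.assigned_guide == "g1"

    def test_eight_reads_not_unique(self):
        # sqrt(0.09 / 8) = 0.106 > 0.1: the confidence rule fails at n=8
        call = assign_cell(self._reads({"g1": 8}))
        assert call.category != CellCategory.UNIQUE

    def test_18_2_split_is_category_two(self):
        # p-hat = 0.9 exactly fails the strict > 0.9 rule
        call = assign_cell(self._reads({"g1": 18, "g2": 2}))
        assert call.category == CellCategory.TWO

    def test_unassigned_reads_excluded_from_denominator(self):
        reads = self._reads({"g1": 9}) + [
            ReadAssignment("CB", "U", UNASSIGNED, MatchTier.NONE)] * 5
        call = assign_cell(reads)
        assert call.category == CellCategory.UNIQUE
        assert call.total_reads == 9

    def test_matches_brute_force_oracle(self, rng):
        guides = [f"g{i}" for i in range(5)]
        for _ in range(300):
            counts = {g: int(rng.integers(0, 14)) for g in guides}
            counts = {g: c for g, c in counts.items() if c > 0}
            if not counts:
                continue
            call = assign_cell(self._reads(counts))
            assert call.category.value == brute_force_cell_call(counts)

    def test_vectorised_calls_equal_scalar_rule(self, rng):
        rows = []
        for b in range(200):
            for g in rng.choice([f"g{i}" for i in range(4)], size=int(rng.integers(1, 25))):
                rows.append((f"CB{b:03d}", "U", g, "exact"))
        table = pd.DataFrame(rows, columns=["cell_barcode", "umi", "guide_id", "tier"])
        vec = assign_cells(table)
        for barcode, grp in table.groupby("cell_barcode"):
            counts = grp["guide_id"].value_counts().to_dict()
            assert vec.loc[barcode, "category"] == brute_force_cell_call(counts)

    def test_counts_conservation(self, rng):
        rows = []
        for b in range(150):
            n = int(rng.integers(0, 20))
            for _ in range(n):
                g = UNASSIGNED if rng.random() < 0.3 else f"g{int(rng.integers(3))}"
                rows.append((f"CB{b:03d}", "U", g, "exact"))
        table = pd.DataFrame(rows, columns=["cell_barcode", "umi", "guide_id", "tier"])
        calls = assign_cells(table)
        assert len(calls) == table["cell_barcode"].nunique()
        assert set(calls["category"]) <= {c.value for c in CellCategory}


class TestMatchBarcodes:
    def test_empty_intersection(self):
        df = pd.DataFrame({"category": ["unique"]}, index=pd.Index(["AAAA"], name="barcode"))
        assert len(match_barcodes(df, {"CCCC"})) == 0

    def test_intersection_by_set_arithmetic(self, rng):
        barcodes = [f"B{i:02d}" for i in range(40)]
        df = pd.DataFrame({"category": "unique"}, index=pd.Index(barcodes, name="barcode"))
        expr = set(rng.choice(barcodes, size=17, replace=False)) | {"ZZZ"}
        kept = match_barcodes(df, expr)
        assert set(kept.index) == set(barcodes) & expr

    def test_noiseless_simulation_full_recovery(self):
        cfg = small_config(base_error_rate=0.0, contamination_rate=0.0, doublet_rate=0.0,
                           seed=23)
        rng = np.random.default_rng(23)
        lib = generate_library(cfg, rng)
        _, truth = generate_cells(cfg, lib, rng)
        reads = generate_amplicon_reads(cfg, truth, lib, rng)
        calls = assign_cells(match_reads(reads, lib))
        uniq = calls.loc[calls["category"] == "unique"]
        truth_guides = truth.singlet_guides
        common = uniq.index.intersection(truth_guides.index)
        assert (uniq.loc[common, "assigned_guide"] == truth_guides.loc[common]).all()
        # every singlet with >= 9 reads is uniquely recovered
        enough = calls["total_reads"] >= 9
        singlets = calls.index.isin(truth_guides.index)
        assert (calls.loc[enough & singlets, "category"] == "unique").all()
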