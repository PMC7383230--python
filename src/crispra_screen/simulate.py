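"""Seeded synthetic CRISPRa-screen generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* a guide whitelist with minimum pairwise Levenshtein distance >= 4;
* cells x genes UMI counts drawn from a negative binomial (variance
  mu + phi mu^2) with log-normal library sizes and a Beta-distributed
  mitochondrial fraction;
* a rare binary ZGA-like state with a continuous per-cell intensity that
  scales a designated signature gene set and the MERVL repeat family,
  active in ~2% of baseline cells and ~8.6% of cells carrying a true-hit
  sgRNA;
* CRISPRa activation of each targeting sgRNA's own target gene;
* amplicon reads (23-nt vector arm + 20-nt protospacer + 23-nt arm) with
  per-base substitution errors and sgRNA contamination; and
* repeat-derived reads sampled from per-family instance sequences with
  cell barcode + UMI.

All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .guides import GuideLibrary, levenshtein
from .io import SequencedRead, write_fastq
from .screen_data import GroundTruth, ScreenMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MITO_PREFIX = "mt-"


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n random DNA k-mers as an (n, length) uint8 matrix."""
    return _BASES[rng.integers(0, 4, size=(n, length))]


def _kmers_to_strings(mat: np.ndarray) -> np.ndarray:
    return mat.view(f"S{mat.shape[1]}").ravel().astype("U")


def _unique_barcodes(rng: np.random.Generator, n: int, length: int = 16) -> np.ndarray:
    out = _kmers_to_strings(_random_kmers(rng, n, length))
    while True:
        _, idx, counts = np.unique(out, return_index=True, return_counts=True)
        if (counts == 1).all():
            return out
        dup_mask = np.ones(n, dtype=bool)
        dup_mask[idx] = False
        out[dup_mask] = _kmers_to_strings(_random_kmers(rng, int(dup_mask.sum()), length))


def generate_library(config: SimulationConfig, rng: np.random.Generator | None = None) -> GuideLibrary:
    """Draw a guide whitelist with the configured design and a minimum
    pairwise Levenshtein distance of ``config.min_guide_distance``.

    Raises ``ValueError`` if the distance constraint cannot be satisfied
    at the configured protospacer length within the attempt budget.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = config.total_guides
    L = config.protospacer_length
    if 4 ** L < size:
        raise ValueError("protospacer length too short for requested library size")

    import edlib

    accepted: list = []
    budget = 200 * size + 1000
    attempts = 0
    while len(accepted) < size:
        if attempts >= budget:
            raise ValueError(
                f"could not build {size} protospacers of length {L} with minimum "
                f"pairwise distance {config.min_guide_distance}"
            )
        batch = _kmers_to_strings(_random_kmers(rng, min(size, 512), L))
        for cand in batch:
            attempts += 1
            ok = all(
                edlib.align(cand, acc, mode="NW", task="distance",
                            k=config.min_guide_distance - 1)["editDistance"] == -1
                for acc in accepted
            )
            if ok:
                accepted.append(cand)
                if len(accepted) == size:
                    break

    target_genes = [f"Gene{i + 1:04d}" for i in range(config.n_target_genes)]
    rows = []
    k = 0
    for gene in target_genes:
        for j in range(config.sgrnas_per_target):
            rows.append((f"sg-{gene}-{j + 1}", accepted[k], gene, True))
            k += 1
    for j in range(config.n_nontargeting):
        rows.append((f"sgNT-{j + 1:02d}", accepted[k], "", False))
        k += 1
    guides = pd.DataFrame(rows, columns=["guide_id", "protospacer", "target_gene", "is_targeting"])
    return GuideLibrary(guides)


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene universe: CRISPRa targets first, then the
    signature set, mitochondrial genes last."""
    n_regular = config.n_genes - config.n_mito_genes
    gene_ids = [f"Gene{i + 1:04d}" for i in range(n_regular)]
    gene_ids += [f"{_MITO_PREFIX}{i + 1:02d}" for i in range(config.n_mito_genes)]
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_mito[n_regular:] = True
    is_signature = np.zeros(config.n_genes, dtype=bool)
    sig_start = config.n_target_genes
    is_signature[sig_start:sig_start + config.n_signature_genes] = True
    is_target = np.zeros(config.n_genes, dtype=bool)
    is_target[:config.n_target_genes] = True
    return pd.DataFrame(
        {"is_mito": is_mito, "is_signature": is_signature, "is_target": is_target},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _pick_true_hits(config: SimulationConfig, library: GuideLibrary,
                    rng: np.random.Generator) -> set:
    targeting = library.guides.loc[library.guides["is_targeting"]]
    if config.n_true_hits == 0:
        return set()
    if config.hits_share_gene and config.sgrnas_per_target > 1:
        genes = targeting["target_gene"].unique()
        n_genes = math.ceil(config.n_true_hits / config.sgrnas_per_target)
        chosen = rng.choice(genes, size=n_genes, replace=False)
        ids = targeting.loc[targeting["target_gene"].isin(chosen), "guide_id"].tolist()
        return set(sorted(ids)[: config.n_true_hits])
    ids = rng.choice(targeting["guide_id"].to_numpy(), size=config.n_true_hits, replace=False)
    return set(ids.tolist())


def generate_cells(config: SimulationConfig, library: GuideLibrary,
                   rng: np.random.Generator | None = None) -> tuple:
    """Simulate the cells x genes and cells x repeat-family count matrices.

    Returns ``(ScreenMatrix, GroundTruth)``. Identical config and seed
    give bit-identical outputs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_cells = len(library) * config.cells_per_sgrna
    n_genes = config.n_genes
    if n_cells == 0 or n_genes == 0:
        raise ValueError("zero cells or zero genes requested")

    genes = _gene_table(config)
    guide_ids = library.guides["guide_id"].to_numpy()
    true_hits = _pick_true_hits(config, library, rng)

    # cell -> guide(s)
    guide_1 = np.repeat(guide_ids, config.cells_per_sgrna)
    is_doublet = rng.random(n_cells) < config.doublet_rate
    other = rng.integers(0, len(guide_ids) - 1, size=n_cells)
    own_idx = np.repeat(np.arange(len(guide_ids)), config.cells_per_sgrna)
    other = np.where(other >= own_idx, other + 1, other)
    guide_2 = np.where(is_doublet, guide_ids[other], "")

    barcodes = _unique_barcodes(rng, n_cells)

    # ZGA-like state and continuous intensity
    is_hit_1 = np.isin(guide_1, list(true_hits))
    is_hit_2 = np.isin(guide_2, list(true_hits))
    state_prob = np.where(is_hit_1 | is_hit_2, config.hit_state_prob, config.baseline_state_prob)
    in_state = rng.random(n_cells) < state_prob
    sigma = config.state_intensity_sigma
    intensity = np.where(
        in_state, np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=n_cells)), 0.0
    )

    # library size and mitochondrial fraction; a small planted fraction of
    # low-quality cells (tiny libraries, high mito) for QC to remove
    is_lowq = rng.random(n_cells) < config.lowquality_cell_rate
    libsize = np.where(is_lowq, config.lowquality_libsize, config.median_libsize) * np.exp(
        rng.normal(0.0, config.libsize_lognormal_sigma, size=n_cells)
    )
    mito_frac = np.where(
        is_lowq,
        rng.beta(config.lowquality_mito_beta_a, config.lowquality_mito_beta_b, size=n_cells),
        rng.beta(config.mito_beta_a, config.mito_beta_b, size=n_cells),
    )

    # relative gene means
    mito_mask = genes["is_mito"].to_numpy()
    base = np.exp(rng.normal(0.0, config.gene_mean_lognormal_sigma, size=n_genes))
    base_rel = np.where(~mito_mask, base, 0.0)
    base_rel = base_rel / base_rel.sum()
    mito_rel = np.where(mito_mask, base, 0.0)
    if mito_mask.any():
        mito_rel = mito_rel / mito_rel.sum()

    mu = np.empty((n_cells, n_genes), dtype=np.float32)
    mu[:] = (base_rel + mito_rel).astype(np.float32)[None, :]

    # CRISPRa activation of each cell's target gene(s)
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    target_of = library.guides.set_index("guide_id")["target_gene"].to_dict()
    act = 2.0 ** config.activation_log2fc
    for guide_col in (guide_1, guide_2):
        tg = np.array([target_of.get(g, "") for g in guide_col])
        has_target = tg != ""
        rows = np.flatnonzero(has_target)
        cols = np.array([gene_pos[t] for t in tg[has_target]], dtype=int)
        mu[rows, cols] *= act

    # ZGA-like state scales signature genes by the planted intensity
    sig_idx = np.flatnonzero(genes["is_signature"].to_numpy())
    state_rows = np.flatnonzero(in_state)
    if state_rows.size and sig_idx.size:
        scale = (1.0 + (config.signature_fold - 1.0) * intensity[state_rows]).astype(np.float32)
        mu[np.ix_(state_rows, sig_idx)] *= scale[:, None]

    # per-cell renormalisation: rows sum to 1 with the drawn mito share
    mito_idx = np.flatnonzero(mito_mask)
    total = mu.sum(axis=1, dtype=np.float64)
    mt_sum = mu[:, mito_idx].sum(axis=1, dtype=np.float64) if mito_idx.size else np.zeros(n_cells)
    nm_sum = total - mt_sum
    f_nm = ((1.0 - mito_frac) / nm_sum) * libsize
    mu *= f_nm.astype(np.float32)[:, None]
    if mito_idx.size:
        f_mt = (mito_frac / mt_sum) * libsize
        mu[:, mito_idx] *= (f_mt / f_nm).astype(np.float32)[:, None]

    counts = _sample_nb(rng, mu, config.nb_dispersion)

    # repeat-family molecules
    fam_names = list(config.repeat_families)
    fam_mu = np.empty((n_cells, len(fam_names)), dtype=np.float32)
    rel_lib = (libsize / config.median_libsize).astype(np.float32)
    for j, fam in enumerate(fam_names):
        fam_mu[:, j] = config.repeat_means[fam] * rel_lib
    if "MERVL" in fam_names and state_rows.size:
        jm = fam_names.index("MERVL")
        fam_mu[state_rows, jm] *= (
            1.0 + (config.mervl_state_fold - 1.0) * intensity[state_rows]
        ).astype(np.float32)
    repeat_counts = _sample_nb(rng, fam_mu, config.nb_dispersion)
    repeats = pd.DataFrame(repeat_counts, index=pd.Index(barcodes, name="barcode"),
                           columns=fam_names)

    cells = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    matrix = ScreenMatrix(counts, cells, genes, repeats).with_qc_fields()

    bindex = pd.Index(barcodes, name="barcode")
    truth = GroundTruth(
        true_hit_sgrnas=true_hits,
        cell_guides=pd.DataFrame(
            {"guide_1": guide_1, "guide_2": guide_2, "is_doublet": is_doublet}, index=bindex
        ),
        cell_state=pd.Series(in_state, index=bindex, name="state"),
        cell_factor_value=pd.Series(intensity, index=bindex, name="factor_value"),
        signature_genes=genes.index[genes["is_signature"]].tolist(),
        per_gene_base_mean=pd.Series(base_rel + mito_rel, index=genes.index, name="base_mean"),
        repeat_molecules=repeats.copy(),
        is_low_quality=pd.Series(is_lowq, index=bindex, name="is_low_quality"),
    )
    return matrix, truth


def _sample_nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
               chunk: int = 4096) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (gamma-Poisson
    mixture); dispersion 0 reduces to Poisson. Chunked to bound memory."""
    out = np.empty(mu.shape, dtype=np.int32)
    for start in range(0, mu.shape[0], chunk):
        sl = slice(start, start + chunk)
        lam = mu[sl]
        if dispersion > 0:
            g = rng.standard_gamma(1.0 / dispersion, size=lam.shape, dtype=np.float32)
            lam = g * (dispersion * lam)
        out[sl] = rng.poisson(np.asarray(lam, dtype=np.float64))
    return out


@dataclass
class ReadSet:
    """A set of simulated reads as parallel arrays, iterable as
    SequencedRead records."""

    cell_barcodes: np.ndarray
    umis: np.ndarray
    sequences: np.ndarray

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        for cb, umi, seq in zip(self.cell_barcodes, self.umis, self.sequences):
            yield SequencedRead(str(cb), str(umi), str(seq))

    def to_fastq(self, path) -> None:
        write_fastq(path, self.cell_barcodes, self.umis, self.sequences)


def generate_amplicon_reads(config: SimulationConfig, truth: GroundTruth,
                            library: GuideLibrary,
                            rng: np.random.Generator | None = None) -> ReadSet:
    """Simulate sgRNA amplicon reads.

    Each read is 23 nt upstream vector arm + 20 nt protospacer + 23 nt
    downstream arm. Reads carry the cell's true sgRNA except with
    probability ``contamination_rate`` (a uniformly chosen different
    guide); every base is substituted independently with probability
    ``base_error_rate``. Read counts per cell are Poisson.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    barcodes = truth.cell_guides.index.to_numpy()
    gid = library.guides["guide_id"].to_numpy()
    gindex = {g: i for i, g in enumerate(gid)}
    g1 = np.array([gindex[g] for g in truth.cell_guides["guide_1"]])
    g2_raw = truth.cell_guides["guide_2"].to_numpy()
    has_g2 = g2_raw != ""
    g2 = np.where(has_g2, [gindex.get(g, 0) for g in g2_raw], g1)

    n_reads_per_cell = rng.poisson(config.amplicon_reads_per_cell, size=len(barcodes))
    cell_idx = np.repeat(np.arange(len(barcodes)), n_reads_per_cell)
    n_reads = len(cell_idx)

    # guide emitted by each read: either of the cell's guides, then
    # contamination replaces it with a uniformly drawn other guide
    pick_second = rng.random(n_reads) < 0.5
    guide_idx = np.where(pick_second & has_g2[cell_idx], g2[cell_idx], g1[cell_idx])
    contam = rng.random(n_reads) < config.contamination_rate
    if contam.any() and len(gid) > 1:
        alt = rng.integers(0, len(gid) - 1, size=int(contam.sum()))
        alt = np.where(alt >= guide_idx[contam], alt + 1, alt)
        guide_idx[contam] = alt

    templates = np.array(
        [
            np.frombuffer(
                (library.upstream_context + p + library.downstream_context).encode(), dtype=np.uint8
            )
            for p in library.guides["protospacer"]
        ]
    )
    reads = templates[guide_idx].copy()
    if config.base_error_rate > 0:
        err = rng.random(reads.shape, dtype=np.float32) < config.base_error_rate
        pos = np.flatnonzero(err.ravel())
        if pos.size:
            flat = reads.ravel()
            lut = np.zeros(256, dtype=np.uint8)
            lut[_BASES] = np.arange(4)
            cur = lut[flat[pos]]
            flat[pos] = _BASES[(cur + rng.integers(1, 4, size=pos.size)) % 4]

    umis = _kmers_to_strings(_random_kmers(rng, n_reads, 10))
    return ReadSet(
        cell_barcodes=barcodes[cell_idx],
        umis=umis,
        sequences=_kmers_to_strings(reads),
    )


def generate_repeat_reference(config: SimulationConfig,
                              rng: np.random.Generator | None = None):
    """Random per-family repeat instance sequences for the simplified
    repeat mapper."""
    from .repeats import RepeatFamilyRef, build_repeat_reference

    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    families = []
    for fam in config.repeat_families:
        instances = [
            str(s)
            for s in _kmers_to_strings(
                _random_kmers(rng, config.repeat_instances_per_family,
                              config.repeat_instance_length)
            )
        ]
        families.append((fam, instances))
    return build_repeat_reference(families)


def generate_repeat_reads(config: SimulationConfig, truth: GroundTruth,
                          reference, rng: np.random.Generator | None = None) -> ReadSet:
    """Simulate repeat-derived reads realising the planted molecule table.

    Every planted molecule emits at least one read; reads are windows of
    the family's instance sequences, labelled with the cell barcode and a
    per-(cell, family) unique UMI, so that UMI collapsing recovers the
    molecule table exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    refs = {r.family_name: r for r in reference}
    if not refs:
        raise ValueError("empty repeat reference")
    read_len = config.repeat_read_length
    for ref in refs.values():
        if any(len(inst) < read_len for inst in ref.instance_sequences):
            raise ValueError(
                f"repeat instance shorter than read length {read_len} in family {ref.family_name}"
            )
    mol = truth.repeat_molecules
    out_cb, out_umi, out_seq = [], [], []
    fam_names = [f for f in mol.columns if f in refs]
    umi_space = 4 ** 10
    for fam in fam_names:
        counts = mol[fam].to_numpy()
        cells_with = np.flatnonzero(counts > 0)
        for ci in cells_with:
            m = int(counts[ci])
            # unique UMIs within the (cell, family) group
            stride = umi_space // max(m, 1)
            base_off = int(rng.integers(0, max(stride, 1)))
            umi_ints = (base_off + np.arange(m) * stride) % umi_space
            n_extra = rng.poisson(max(config.repeat_reads_per_molecule - 1.0, 0.0), size=m)
            reads_per_mol = 1 + n_extra
            barcode = mol.index[ci]
            ref = refs[fam]
            for mi in range(m):
                umi = _int_to_umi(int(umi_ints[mi]))
                for _ in range(int(reads_per_mol[mi])):
                    inst = ref.instance_sequences[int(rng.integers(0, len(ref.instance_sequences)))]
                    start = int(rng.integers(0, len(inst) - read_len + 1))
                    out_cb.append(barcode)
                    out_umi.append(umi)
                    out_seq.append(inst[start:start + read_len])
    return ReadSet(np.array(out_cb), np.array(out_umi), np.array(out_seq))


def _int_to_umi(x: int, length: int = 10) -> str:
    letters = "ACGT"
    return "".join(letters[(x >> (2 * i)) & 3] for i in range(length))


def simulate_screen(config: SimulationConfig) -> dict:
    """Generate a complete synthetic screen: library, counts, truth and
    amplicon reads, all derived from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    library = generate_library(config, rng)
    matrix, truth = generate_cells(config, library, rng)
    reads = generate_amplicon_reads(config, truth, library, rng)
    return {"library": library, "matrix": matrix, "truth": truth, "amplicon_reads": reads}
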