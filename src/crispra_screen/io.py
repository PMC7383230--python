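"""Plain-text readers and writers: FASTQ with barcode/UMI-encoding read
names, and small TSV helpers.

Read names follow the convention ``CB:<16nt>_UMI:<10nt>`` so that cell
barcode and UMI travel with each read in a single FASTQ (a separate
barcode FASTQ dialect is supported on reading).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SequencedRead:
    cell_barcode: str
    umi: str
    sequence: str


def encode_read_name(barcode: str, umi: str) -> str:
    return f"CB:{barcode}_UMI:{umi}"


def decode_read_name(name: str) -> tuple:
    name = name.split()[0]
    if not name.startswith("CB:") or "_UMI:" not in name:
        raise ValueError(f"read name does not encode barcode/UMI: {name!r}")
    cb, umi = name[3:].split("_UMI:", 1)
    return cb, umi


def write_fastq(path, barcodes, umis, sequences) -> None:
    chunks = []
    for cb, umi, seq in zip(barcodes, umis, sequences):
        chunks.append(f"@{encode_read_name(cb, umi)}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(path, "w") as fh:
        fh.write("".join(chunks))


def read_fastq(path, barcode_fastq=None):
    """Yield SequencedRead from FASTQ.

    If ``barcode_fastq`` is given, barcodes and UMIs are taken from the
    paired file (16 nt barcode + 10 nt UMI per read) instead of the read
    name.
    """
    if barcode_fastq is None:
        with open(path) as fh:
            while True:
                name = fh.readline()
                if not name:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                cb, umi = decode_read_name(name[1:].strip())
                yield SequencedRead(cb, umi, seq)
    else:
        with open(path) as fh, open(barcode_fastq) as bh:
            while True:
                name = fh.readline()
                if not name:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                bh.readline()
                bseq = bh.readline().strip()
                bh.readline()
                bh.readline()
                yield SequencedRead(bseq[:16], bseq[16:26], seq)


def read_fastq_arrays(path):
    """Read a name-encoded FASTQ into (barcodes, umis, sequences) arrays."""
    barcodes, umis, seqs = [], [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        cb, umi = decode_read_name(lines[i][1:])
        barcodes.append(cb)
        umis.append(umi)
        seqs.append(lines[i + 1])
    return np.array(barcodes), np.array(umis), np.array(seqs)


def write_fasta(path, records) -> None:
    """records: iterable of (name, description, sequence)."""
    with open(path, "w") as fh:
        for name, desc, seq in records:
            header = f">{name} {desc}".rstrip()
            fh.write(f"{header}\n{seq}\n")


def read_repeat_fasta(path):
    """Parse repeat instances from FASTA; family name is taken from the
    description field (``>instance_id family=<name>`` or the whole
    description). Returns {family: [sequences]}."""
    families: dict = {}
    name, desc, seq = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    families.setdefault(desc, []).append("".join(seq))
                parts = line[1:].split(None, 1)
                name = parts[0]
                d = parts[1] if len(parts) > 1 else parts[0]
                desc = d.split("family=", 1)[1].strip() if "family=" in d else d.strip()
                seq = []
            else:
                seq.append(line.strip())
    if name is not None:
        families.setdefault(desc, []).append("".join(seq))
    return families


def write_tsv(df: pd.DataFrame, path, index=True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
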