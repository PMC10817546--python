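"""Plain-text readers/writers: FASTA, FASTQ (Phred+33), TSV, Newick, JSON.

Sequences are uppercased and U is mapped to T on input; anything outside
ACGTN is rejected with the offending record and position.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from skbio import TreeNode

from .readprep import FastqRead

__all__ = [
    "clean_sequence",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_newick",
    "write_newick",
    "read_json",
    "write_json",
]

_VALID = set("ACGTN")


def clean_sequence(seq: str, context: str = "") -> str:
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise ValueError(f"invalid base {ch!r} at position {i} {context}".strip())
    return s


def read_fasta(path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, clean_sequence("".join(chunks), f"(record {header})")))
                header = line[1:].split()[0]
                chunks = []
            elif header is None:
                raise ValueError(f"line {lineno}: sequence before first header")
            else:
                chunks.append(line)
    if header is not None:
        records.append((header, clean_sequence("".join(chunks), f"(record {header})")))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path, sample_id: str = "") -> list[FastqRead]:
    reads: list[FastqRead] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: FASTQ record count not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: sequence/quality length mismatch at line {i + 1}")
        seq = clean_sequence(seq, f"(line {i + 2})")
        reads.append(FastqRead(head[1:].split()[0], seq, [ord(c) - 33 for c in qual], sample_id))
    return reads


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_newick(path_or_str) -> TreeNode:
    if isinstance(path_or_str, (str, Path)) and Path(str(path_or_str)).exists():
        return TreeNode.read(str(path_or_str), format="newick")
    from io import StringIO

    return TreeNode.read(StringIO(str(path_or_str)), format="newick")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def _default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
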