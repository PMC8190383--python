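"""Inter-stage file plumbing: FASTQ in, commented TSV in/out, manifests.

Every TSV written by the pipeline starts with ``#`` comment lines carrying
the tool version, a short configuration hash, and the seed, so any stage
can be re-run and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO


class IOFormatError(ValueError):
    pass


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, np.ndarray]]:
    """Yield (read id, sequence, phred qualities) from a Phred+33 FASTQ."""
    index = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            index += 1
            qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
            yield rec.id, str(rec.seq).upper(), qual
    except ValueError as exc:
        raise IOFormatError(f"malformed FASTQ record at index {index + 1}: {exc}") from exc


def config_digest(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_comments(version: str, seed: Optional[int], digest: str, extra: Optional[dict] = None) -> list[str]:
    lines = [
        f"# ighrep v{version}",
        f"# config_sha={digest}",
        f"# seed={seed}",
    ]
    for key, value in (extra or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    comments: Optional[list[str]] = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, index_col: Optional[str] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_manifest(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
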