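"""Ground-truth V(D)J recombination simulator.

Generates IGH repertoire reads with the statistical structure the analysis
downstream assumes: multinomial segment usage at the clone level,
exonucleolytic trimming (geometric per junction end, never crossing an
anchor codon), palindromic (P) extensions at untrimmed ends, non-templated
(N) insertions at the V-D and D-J joins, isotype-specific somatic
hypermutation in the V region, power-law clone sizes, and independent
per-base sequencing error per read.  Every read carries a TruthRecord, so
annotator accuracy, SHM recovery and germline-index recovery can be scored
exactly.

A read is assembled as::

    V[0 : len-v_trim] + P + N1 + D[d5 : len-d3] + N2 + P + J[j_trim :] + C

and the junction truth is the span from the first base of the V 2nd-CYS
codon through the last base of the J-TRP codon.  SHM is applied 5' of the
V anchor only, so junction truth is exact and anchor codons survive
mutation; sequencing error is unrestricted (but drawn disjoint from SHM
positions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineSet, GermlineSegment, isotype_class

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default per-base SHM rates by isotype class: naive-compartment isotypes
#: (IgM/IgD) mutate less than class-switched ones.
DEFAULT_SHM_BY_ISOTYPE = {"IGHM": 0.01, "IGHD": 0.01, "default": 0.03}

TRUTH_COLUMNS = [
    "read_id", "clone_id", "v_call", "d_call", "j_call", "c_call",
    "v_trim", "d5_trim", "d3_trim", "j_trim",
    "p_v", "p_d5", "p_d3", "p_j", "n1", "n2",
    "junction", "junction_aa", "junction_length", "germline_junction_nt",
    "shm_positions", "error_positions", "productive",
]


class SimulationError(ValueError):
    pass


def _normalize_usage(usage: Optional[dict], ids: list[str], what: str) -> dict[str, float]:
    if usage is None:
        return {i: 1.0 / len(ids) for i in ids}
    missing = set(usage) - set(ids)
    if missing:
        raise SimulationError(f"{what} references unknown segment ids: {sorted(missing)}")
    total = float(sum(usage.values()))
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"{what} must sum to 1 (got {total})")
    return {k: float(v) for k, v in usage.items()}


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults are the package's
    reference conditions (documented in the methods note)."""

    reference: GermlineSet
    v_usage: Optional[dict] = None
    d_usage: Optional[dict] = None
    j_usage: Optional[dict] = None
    c_usage: Optional[dict] = None
    trim_geom_mean: float = 2.0  # mean geometric trim per junction end, nt
    p_nt_prob: float = 0.5  # chance of a P extension at an untrimmed end
    p_len_max: int = 2
    n_insert_mean: float = 4.0  # mean Poisson N length per junction
    shm_rate_by_isotype: dict = field(default_factory=lambda: dict(DEFAULT_SHM_BY_ISOTYPE))
    clone_count: int = 500
    reads_per_sample: int = 5000
    clone_size_alpha: float = 2.5
    seq_error_rate: float = 0.001
    nonproductive_rate: float = 0.10  # forced frameshifts via the N insert
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference.validate_for_annotation()
        self.v_usage = _normalize_usage(self.v_usage, self.reference.ids("V"), "v_usage")
        self.d_usage = _normalize_usage(self.d_usage, self.reference.ids("D"), "d_usage")
        self.j_usage = _normalize_usage(self.j_usage, self.reference.ids("J"), "j_usage")
        self.c_usage = _normalize_usage(self.c_usage, self.reference.ids("C"), "c_usage")
        for name in ("p_nt_prob", "seq_error_rate", "nonproductive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        for iso, r in self.shm_rate_by_isotype.items():
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"shm rate for {iso} must be in [0, 1]")
        if self.clone_count > self.reads_per_sample:
            raise SimulationError("clone_count must not exceed reads_per_sample")
        if self.clone_size_alpha <= 1.0:
            raise SimulationError("clone_size_alpha must exceed 1")
        if self.trim_geom_mean < 0 or self.n_insert_mean < 0:
            raise SimulationError("trim and insertion means must be non-negative")

    def shm_rate_for(self, c_call: str) -> float:
        iso = isotype_class(c_call)
        if c_call in self.shm_rate_by_isotype:
            return self.shm_rate_by_isotype[c_call]
        if iso in self.shm_rate_by_isotype:
            return self.shm_rate_by_isotype[iso]
        return self.shm_rate_by_isotype.get("default", 0.0)

    def digest(self) -> str:
        """Short stable hash of the configuration (reference ids included)."""
        payload = {
            k: v for k, v in asdict(self).items() if k != "reference"
        }
        payload["reference"] = sorted(self.reference.segments)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class TruthRecord:
    """Per-read ground truth; one rearrangement is shared by all reads of
    a clone, sequencing-error positions differ per read."""

    read_id: str
    clone_id: int
    v_call: str
    d_call: str
    j_call: str
    c_call: str
    v_trim: int
    d5_trim: int
    d3_trim: int
    j_trim: int
    p_v: int
    p_d5: int
    p_d3: int
    p_j: int
    n1: int
    n2: int
    junction: str
    junction_aa: str
    germline_junction_nt: int
    shm_positions: tuple
    error_positions: tuple
    productive: bool

    @property
    def junction_length(self) -> int:
        return len(self.junction)

    def to_row(self) -> dict:
        d = asdict(self)
        d["junction_length"] = self.junction_length
        d["shm_positions"] = ",".join(map(str, self.shm_positions))
        d["error_positions"] = ",".join(map(str, self.error_positions))
        return {k: d[k] for k in TRUTH_COLUMNS}


def _geometric_trim(rng: np.random.Generator, mean: float, cap: int) -> int:
    """Geometric (support 0,1,2,...) trim with the given mean, resampled
    until it does not cross the anchor-protecting cap."""
    if mean <= 0 or cap <= 0:
        return 0
    p = 1.0 / (1.0 + mean)
    for _ in range(1000):
        t = int(rng.geometric(p) - 1)  # numpy geometric has support 1..inf
        if t <= cap:
            return t
    return cap


def _p_nucleotides(rng: np.random.Generator, end_seq: str, cfg: SimulationConfig,
                   five_prime: bool) -> str:
    """Palindromic extension: reverse complement of the terminal bases.

    For a 3' end the P nucleotides extend past the end; for a 5' end they
    are prepended before the start.
    """
    if cfg.p_len_max <= 0 or rng.random() >= cfg.p_nt_prob:
        return ""
    k = int(rng.integers(1, cfg.p_len_max + 1))
    k = min(k, len(end_seq))
    if five_prime:
        chunk = end_seq[:k]
    else:
        chunk = end_seq[-k:]
    return "".join(_COMP[b] for b in reversed(chunk))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _choose(rng: np.random.Generator, usage: dict[str, float]) -> str:
    ids = sorted(usage)
    probs = np.array([usage[i] for i in ids])
    return ids[int(rng.choice(len(ids), p=probs / probs.sum()))]


def apply_shm(
    sequence: str,
    region: tuple[int, int],
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Point-mutate a region of a sequence at a per-base rate.

    Substitutions only, each to one of the 3 alternative bases drawn
    uniformly; returns the mutated sequence and the changed positions.
    """
    if not 0.0 <= rate <= 1.0:
        raise SimulationError("rate must be in [0, 1]")
    start, end = region
    if not 0 <= start <= end <= len(sequence):
        raise SimulationError("region outside sequence")
    if rate == 0.0 or end == start:
        return sequence, []
    mask = rng.random(end - start) < rate
    positions = (np.nonzero(mask)[0] + start).tolist()
    if not positions:
        return sequence, []
    seq = list(sequence)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(seq), positions


def simulate_rearrangement(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, TruthRecord]:
    """Draw one clone-level rearrangement: segment choice, trimming, P/N
    nucleotides, frame adjustment, SHM.  Sequencing error is applied later,
    per read."""
    ref = config.reference
    v = ref[_choose(rng, config.v_usage)]
    d = ref[_choose(rng, config.d_usage)]
    j = ref[_choose(rng, config.j_usage)]
    c = ref[_choose(rng, config.c_usage)]

    v_cap = len(v.sequence) - (v.anchor + 3)  # never trim into the Cys codon
    j_cap = j.anchor  # never trim into the Trp codon
    v_trim = _geometric_trim(rng, config.trim_geom_mean, v_cap)
    d5_trim = _geometric_trim(rng, config.trim_geom_mean, len(d.sequence))
    d3_trim = _geometric_trim(rng, config.trim_geom_mean, len(d.sequence) - d5_trim)
    j_trim = _geometric_trim(rng, config.trim_geom_mean, j_cap)

    v_part = v.sequence[: len(v.sequence) - v_trim]
    d_part = d.sequence[d5_trim : len(d.sequence) - d3_trim]
    j_part = j.sequence[j_trim:]

    p_v = _p_nucleotides(rng, v_part, config, five_prime=False) if v_trim == 0 else ""
    p_d5 = _p_nucleotides(rng, d_part, config, five_prime=True) if (d5_trim == 0 and d_part) else ""
    p_d3 = _p_nucleotides(rng, d_part, config, five_prime=False) if (d3_trim == 0 and d_part) else ""
    p_j = _p_nucleotides(rng, j_part, config, five_prime=True) if j_trim == 0 else ""

    v_contrib = len(v_part) - v.anchor  # junction nt provided by V (>= 3)
    j_contrib = j.anchor - j_trim + 3  # junction nt provided by J (>= 3)
    base_len = (
        v_contrib + len(p_v) + len(p_d5) + len(d_part) + len(p_d3)
        + len(p_j) + j_contrib
    )
    # Frame control by rejection-sampling the N lengths: the marginal N
    # distribution keeps its configured mean, unlike padding the insert.
    want_in_frame = rng.random() >= config.nonproductive_rate
    n1 = int(rng.poisson(config.n_insert_mean))
    n2 = int(rng.poisson(config.n_insert_mean))
    for _ in range(200):
        if ((base_len + n1 + n2) % 3 == 0) == want_in_frame:
            break
        n1 = int(rng.poisson(config.n_insert_mean))
        n2 = int(rng.poisson(config.n_insert_mean))
    junction_len = base_len + n1 + n2

    n1_seq = _random_nt(rng, n1)
    n2_seq = _random_nt(rng, n2)
    read = v_part + p_v + n1_seq + p_d5 + d_part + p_d3 + n2_seq + p_j + j_part + c.sequence

    junction_start = v.anchor
    junction_end = junction_start + junction_len
    # SHM strictly 5' of the V anchor: junction truth stays exact
    read, shm_positions = apply_shm(
        read, (0, v.anchor), config.shm_rate_for(c.id), rng
    )
    junction = read[junction_start:junction_end]
    germline_nt = v_contrib + len(d_part) + j_contrib
    n_total = n1 + n2
    p_total = len(p_v) + len(p_d5) + len(p_d3) + len(p_j)
    assert germline_nt + n_total + p_total == junction_len

    if junction_len % 3 == 0:
        frame = v.anchor % 3  # V reading frame relative to read start
        aa = str(Seq(read[frame:junction_end]).translate())
        junction_aa = str(Seq(junction).translate())
        productive = "*" not in aa
    else:
        junction_aa = ""
        productive = False

    truth = TruthRecord(
        read_id="", clone_id=-1,
        v_call=v.id, d_call=d.id, j_call=j.id, c_call=c.id,
        v_trim=v_trim, d5_trim=d5_trim, d3_trim=d3_trim, j_trim=j_trim,
        p_v=len(p_v), p_d5=len(p_d5), p_d3=len(p_d3), p_j=len(p_j),
        n1=n1, n2=n2,
        junction=junction, junction_aa=junction_aa,
        germline_junction_nt=germline_nt,
        shm_positions=tuple(shm_positions), error_positions=(),
        productive=productive,
    )
    return read, truth


def _clone_sizes(rng: np.random.Generator, k: int, total: int, alpha: float) -> np.ndarray:
    """Integer clone sizes from a discrete power law, summing exactly to
    ``total`` with every clone kept at size >= 1."""
    weights = rng.zipf(alpha, size=k).astype(float)
    sizes = np.maximum(1, np.floor(total * weights / weights.sum())).astype(int)
    diff = total - sizes.sum()
    order = np.argsort(-sizes, kind="stable")
    i = 0
    while diff != 0:
        idx = order[i % k]
        if diff > 0:
            sizes[idx] += 1
            diff -= 1
        elif sizes[idx] > 1:
            sizes[idx] -= 1
            diff += 1
        i += 1
    return sizes


def simulate_sample(
    config: SimulationConfig, sample_id: str = "sample"
) -> tuple[list[tuple[str, str, np.ndarray]], pd.DataFrame]:
    """Simulate one repertoire sample.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence,
    phred_qualities)`` tuples — base quality Q37, sequencing-error
    positions flagged Q15 — and ``truth`` has one row per read.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _clone_sizes(rng, config.clone_count, config.reads_per_sample, config.clone_size_alpha)
    reads: list[tuple[str, str, np.ndarray]] = []
    rows: list[dict] = []
    read_no = 0
    for clone_id, size in enumerate(sizes):
        seq, truth = simulate_rearrangement(config, rng)
        shm_set = set(truth.shm_positions)
        for _ in range(size):
            read_no += 1
            rid = f"{sample_id}_r{read_no:06d}"
            qual = np.full(len(seq), 37, dtype=np.int8)
            if config.seq_error_rate > 0:
                mask = rng.random(len(seq)) < config.seq_error_rate
                err_positions = [p for p in np.nonzero(mask)[0].tolist() if p not in shm_set]
            else:
                err_positions = []
            if err_positions:
                out = list(seq)
                for pos in err_positions:
                    alternatives = [b for b in "ACGT" if b != out[pos]]
                    out[pos] = alternatives[int(rng.integers(0, 3))]
                    qual[pos] = 15
                read_seq = "".join(out)
            else:
                read_seq = seq
            rec = TruthRecord(
                **{**asdict(truth),
                   "read_id": rid, "clone_id": clone_id,
                   "error_positions": tuple(err_positions)}
            )
            reads.append((rid, read_seq, qual))
            rows.append(rec.to_row())
    truth_df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth_df


def write_fastq(reads: list[tuple[str, str, np.ndarray]], path: str | Path) -> None:
    """Write simulated reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            qstr = "".join(chr(int(q) + 33) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
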