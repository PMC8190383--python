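"""Per-sample repertoire summary features.

Given a collapsed (clonotype-level) rearrangement table this module
computes segment/family/isotype usage frequencies, Shannon and inverse
Simpson diversity, the CDR-H3 (junction, anchors included) length
distribution, mean normalized Kyte-Doolittle hydrophobicity, the pooled
somatic-hypermutation rate, and the germline index.

Conventions
-----------
* The diversity "species" is the collapsed clonotype, weighted by its
  ``duplicate_count`` (read abundance):

      Shannon = -sum_i (n_i/N) log2(n_i/N)      [bits]
      Simpson = 1 / sum_i (n_i/N)^2             [inverse form, >= 1]

* Hydrophobicity uses the Kyte-Doolittle hydropathy scale divided by 4.5,
  so Ile -> +1 and Arg -> -1; the residue table is an editable TSV.
* SHM rate is the pooled ratio 100 * sum(mutations) / sum(aligned V nt),
  so long alignments weigh more than short ones.
* Germline index (GI) = junction nucleotides covered by the V/D/J
  alignments divided by junction length, in [0, 1]; low GI means many
  N/P nucleotides.
* ``weighting="clonotype"`` counts each collapsed record once;
  ``"read"`` weights records by duplicate_count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .germline import family_of, isotype_class

KD_NORMALIZATION = 4.5


class MetricsError(ValueError):
    pass


def load_hydropathy_table(path: Optional[str | Path] = None) -> dict[str, float]:
    """Load a residue -> hydropathy mapping from a two-column TSV
    (defaults to the packaged Kyte-Doolittle table)."""
    if path is None:
        text = resources.files("ighrep.data").joinpath("kyte_doolittle.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        table[aa] = float(value)
    return table


_KD_TABLE = load_hydropathy_table()


def shannon_index(counts) -> float:
    """Shannon diversity in bits over positive abundance counts."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise MetricsError("counts must be non-empty and positive")
    p = arr / arr.sum()
    return float(-(p * np.log2(p)).sum())


def simpson_index(counts) -> float:
    """Inverse Simpson diversity over positive abundance counts."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise MetricsError("counts must be non-empty and positive")
    p = arr / arr.sum()
    return float(1.0 / (p ** 2).sum())


def kyte_doolittle_index(aa: str, table: Optional[dict[str, float]] = None) -> float:
    """Mean normalized Kyte-Doolittle hydropathy of an amino-acid string,
    in [-1, 1] (raw hydropathy / 4.5)."""
    if not aa:
        raise MetricsError("empty amino-acid string")
    table = table or _KD_TABLE
    total = 0.0
    for i, res in enumerate(aa):
        if res not in table:
            raise MetricsError(f"non-standard residue {res!r} at position {i}")
        total += table[res]
    return total / (len(aa) * KD_NORMALIZATION)


def _weights(table: pd.DataFrame, weighting: str) -> np.ndarray:
    if weighting == "clonotype":
        return np.ones(len(table))
    if weighting == "read":
        return table["duplicate_count"].to_numpy(dtype=float)
    raise MetricsError(f"unknown weighting {weighting!r}")


def gene_usage(
    table: pd.DataFrame,
    seg_class: str,
    level: str = "gene",
    weighting: str = "clonotype",
) -> dict[str, float]:
    """Frequency of each segment (or family) call of one class.

    Records without a call of that class (empty string) are excluded from
    the denominator.
    """
    if table.empty:
        raise MetricsError("no annotated records")
    col = {"V": "v_call", "D": "d_call", "J": "j_call", "C": "c_call"}[seg_class]
    calls = table[col].astype(str)
    mask = calls != ""
    if not mask.any():
        return {}
    calls = calls[mask]
    if level == "family":
        calls = calls.map(family_of)
    elif level != "gene":
        raise MetricsError(f"unknown level {level!r}")
    w = _weights(table, weighting)[mask.to_numpy()]
    sums = pd.Series(w).groupby(calls.to_numpy()).sum()
    total = sums.sum()
    return {k: float(v / total) for k, v in sums.items()}


def isotype_usage(table: pd.DataFrame, weighting: str = "clonotype") -> dict[str, float]:
    """Usage over isotype classes (constant-gene calls collapsed)."""
    gene = gene_usage(table, "C", "gene", weighting)
    out: dict[str, float] = {}
    for call, freq in gene.items():
        iso = isotype_class(call) or call
        out[iso] = out.get(iso, 0.0) + freq
    return out


def _isotype_mask(table: pd.DataFrame, isotype: Optional[str]) -> pd.Series:
    if isotype is None:
        return pd.Series(True, index=table.index)
    return table["c_call"].map(lambda c: isotype_class(c) == isotype or c == isotype)


def shm_rate(table: pd.DataFrame, isotype: Optional[str] = None) -> float:
    """Pooled SHM rate in percent: 100 * sum(mutations) / sum(V nt)."""
    sub = table[_isotype_mask(table, isotype)]
    total_nt = int(sub["v_region_length"].sum()) if len(sub) else 0
    if total_nt == 0:
        raise MetricsError("zero aligned V nucleotides in selection")
    return 100.0 * float(sub["v_mutations"].sum()) / total_nt


def germline_index(germline_junction_nt: int, junction_length: int) -> float:
    """GI of one rearrangement: germline-covered junction nt / junction length."""
    if junction_length <= 0:
        raise MetricsError("junction absent")
    gi = germline_junction_nt / junction_length
    if not 0.0 <= gi <= 1.0:
        raise MetricsError(f"GI {gi} outside [0, 1]")
    return gi


def _junction_table(table: pd.DataFrame, isotype: Optional[str]) -> pd.DataFrame:
    sub = table[_isotype_mask(table, isotype)]
    return sub[(sub["junction_status"] == "ok") & (sub["junction"].astype(str) != "")]


def sample_gi(
    table: pd.DataFrame, isotype: Optional[str] = None, weighting: str = "clonotype"
) -> float:
    """Weighted mean germline index over records with an intact junction."""
    sub = _junction_table(table, isotype)
    if sub.empty:
        raise MetricsError("no records with junction")
    gi = sub["germline_junction_nt"].to_numpy(float) / sub["junction"].str.len().to_numpy(float)
    w = _weights(sub, weighting)
    return float(np.average(gi, weights=w))


def cdr3_length_stats(
    table: pd.DataFrame, isotype: Optional[str] = None, weighting: str = "clonotype"
) -> tuple[dict[int, float], float]:
    """(distribution over junction aa lengths, mean length); lengths count
    both anchor residues (C and W)."""
    sub = _junction_table(table, isotype)
    sub = sub[sub["junction_aa"].astype(str) != ""]
    if sub.empty:
        raise MetricsError("no records with translated junction")
    lengths = sub["junction_aa"].str.len().to_numpy()
    w = _weights(sub, weighting)
    sums = pd.Series(w).groupby(lengths).sum()
    total = sums.sum()
    dist = {int(k): float(v / total) for k, v in sums.items()}
    return dist, float(np.average(lengths, weights=w))


def sample_hydrophobicity(
    table: pd.DataFrame,
    isotype: Optional[str] = None,
    weighting: str = "clonotype",
    hydropathy: Optional[dict[str, float]] = None,
) -> float:
    """Weighted mean normalized Kyte-Doolittle index over junctions."""
    sub = _junction_table(table, isotype)
    sub = sub[sub["junction_aa"].astype(str) != ""]
    sub = sub[~sub["junction_aa"].str.contains(r"\*", na=True)]
    if sub.empty:
        raise MetricsError("no translated junctions")
    values = np.array([kyte_doolittle_index(a, hydropathy) for a in sub["junction_aa"]])
    return float(np.average(values, weights=_weights(sub, weighting)))


@dataclass
class RepertoireProfile:
    """Per-sample feature vector."""

    sample_id: str
    usage: dict = field(default_factory=dict)  # {"V": {...}, "D": ..., "J": ...}
    family_usage: dict = field(default_factory=dict)
    isotype_usage: dict = field(default_factory=dict)
    shannon: float = 0.0
    simpson: float = 1.0
    cdr3_length_mean: float = float("nan")
    cdr3_length_dist: dict = field(default_factory=dict)
    hydrophobicity: float = float("nan")
    shm_rate: float = float("nan")
    gi: float = float("nan")
    per_isotype: dict = field(default_factory=dict)  # iso -> {metric: value}
    clonotype_count: int = 0
    read_count: int = 0

    def features(self) -> dict[str, float]:
        """Flatten into named scalar features for the statistics layer."""
        out: dict[str, float] = {
            "shannon": self.shannon,
            "simpson": self.simpson,
            "cdr3_length": self.cdr3_length_mean,
            "hydrophobicity": self.hydrophobicity,
            "shm_rate": self.shm_rate,
            "gi": self.gi,
        }
        for seg_class, table in self.usage.items():
            for seg_id, freq in table.items():
                out[f"usage:{seg_id}"] = freq
        for fam, freq in self.family_usage.items():
            out[f"family_usage:{fam}"] = freq
        for iso, freq in self.isotype_usage.items():
            out[f"isotype:{iso}"] = freq
        for iso, metrics_ in self.per_isotype.items():
            for name, value in metrics_.items():
                out[f"{name}:{iso}"] = value
        return out


def profile_sample(
    table: pd.DataFrame,
    sample_id: str,
    weighting: str = "clonotype",
    hydropathy: Optional[dict[str, float]] = None,
) -> RepertoireProfile:
    """Compute the full :class:`RepertoireProfile` of one collapsed,
    productive rearrangement table."""
    if table.empty:
        raise MetricsError("no annotated records")
    counts = table["duplicate_count"].to_numpy(int)
    profile = RepertoireProfile(
        sample_id=sample_id,
        clonotype_count=len(table),
        read_count=int(counts.sum()),
        shannon=shannon_index(counts),
        simpson=simpson_index(counts),
    )
    for seg_class in ("V", "D", "J"):
        profile.usage[seg_class] = gene_usage(table, seg_class, "gene", weighting)
    profile.usage["C"] = gene_usage(table, "C", "gene", weighting)
    profile.family_usage = gene_usage(table, "V", "family", weighting)
    profile.isotype_usage = isotype_usage(table, weighting)

    try:
        profile.shm_rate = shm_rate(table)
    except MetricsError:
        pass
    try:
        profile.gi = sample_gi(table, weighting=weighting)
    except MetricsError:
        pass
    try:
        profile.cdr3_length_dist, profile.cdr3_length_mean = cdr3_length_stats(
            table, weighting=weighting
        )
    except MetricsError:
        pass
    try:
        profile.hydrophobicity = sample_hydrophobicity(
            table, weighting=weighting, hydropathy=hydropathy
        )
    except MetricsError:
        pass

    for iso in sorted(profile.isotype_usage):
        entry: dict[str, float] = {}
        for name, fn in (
            ("shm_rate", lambda: shm_rate(table, iso)),
            ("gi", lambda: sample_gi(table, iso, weighting)),
            ("cdr3_length", lambda: cdr3_length_stats(table, iso, weighting)[1]),
            ("hydrophobicity", lambda: sample_hydrophobicity(table, iso, weighting, hydropathy)),
        ):
            try:
                entry[name] = fn()
            except MetricsError:
                continue
        if entry:
            profile.per_isotype[iso] = entry
    return profile


def usage_matrix(profiles: list[RepertoireProfile], seg_class: str) -> pd.DataFrame:
    """Samples x segments frequency matrix (heat-map input); absent
    segments are zero."""
    rows = {p.sample_id: p.usage.get(seg_class, {}) for p in profiles}
    mat = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return mat.reindex(sorted(mat.columns), axis=1)


def profiles_to_frame(profiles: list[RepertoireProfile]) -> pd.DataFrame:
    """Feature matrix (samples x named features); usage features of
    segments absent from a sample are zero-filled."""
    frame = pd.DataFrame.from_dict(
        {p.sample_id: p.features() for p in profiles}, orient="index"
    )
    usage_cols = [c for c in frame.columns if ":" in c and not c.startswith(("shm_rate", "gi", "cdr3", "hydro"))]
    frame[usage_cols] = frame[usage_cols].fillna(0.0)
    frame.index.name = "sample_id"
    return frame.reindex(sorted(frame.columns), axis=1)
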