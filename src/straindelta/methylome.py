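"""Methylome analyses over SMRT kinetics tracks.

SMRT sequencing reports, per genomic position and strand, an interpulse
duration (IPD) ratio — elevated where the template base is chemically
modified — and a Phred-like modification quality value (QV).  This module
enumerates degenerate recognition-motif sites, rolls them up into per-motif
detection summaries, flags overspecified motifs, and compares IPD ratios
between cytosine sequence contexts with a Welch (heteroscedastic) t-test.

Cytosine contexts are mutually exclusive and assigned by specificity:
first C of CGCG, then second C of CGCG, then C followed by G, then any
other C; non-cytosine positions form the background.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import GenomeRecord, reverse_complement

IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

CONTEXTS = ("C_other", "CG_firstC", "CGCG_firstC", "CGCG_secondC")
_CODE = {"background": 0, "C_other": 1, "CG_firstC": 2, "CGCG_firstC": 3,
         "CGCG_secondC": 4}


class MotifError(ValueError):
    """Raised for invalid IUPAC motif patterns."""


class EmptyContextError(RuntimeError):
    """Raised when a requested context has no qualifying positions."""


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate recognition motif with its modified base offset (1-based)."""

    pattern: str
    modified_position: int = 1
    modification_type: str = "m6A"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise MotifError("motif pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC_BASES]
        if bad:
            raise MotifError(f"invalid IUPAC characters: {bad}")
        if not 1 <= self.modified_position <= len(self.pattern):
            raise MotifError("modified_position outside the pattern")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


def partner_motif(motif: IupacMotif) -> IupacMotif:
    """Reverse complement with IUPAC-aware complementation.

    The partner is the recognition sequence as read on the opposite strand;
    for non-palindromic motifs the methyltransferase modifies the partner on
    that strand.  Applying this twice returns the original motif.
    """
    pattern = "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif.pattern))
    return IupacMotif(
        pattern=pattern,
        modified_position=len(motif.pattern) - motif.modified_position + 1,
        modification_type=motif.modification_type,
    )


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    return re.compile("(?=(" + "".join(f"[{IUPAC_BASES[c]}]" for c in pattern) + "))")


def scan_motif(genome: GenomeRecord, motif: IupacMotif) -> list[tuple[int, str]]:
    """All (position, strand) motif sites on both strands.

    The position is the 1-based genomic coordinate of the motif's first base
    as read 5'->3' on the matching strand (so minus-strand sites carry the
    larger genomic coordinate of the occupied interval).  Circular genomes
    wrap across the origin.
    """
    seq = genome.sequence
    length = len(seq)
    plen = len(motif)
    regex = _pattern_regex(motif.pattern)
    extension = plen - 1 if genome.topology == "circular" else 0
    sites: list[tuple[int, str]] = []
    text = seq + seq[:extension]
    for match in regex.finditer(text):
        if match.start() < length:
            sites.append((match.start() + 1, "+"))
    rc = reverse_complement(seq)
    text = rc + rc[:extension]
    for match in regex.finditer(text):
        if match.start() < length:
            sites.append((length - match.start(), "-"))
    return sites


# ---------------------------------------------------------------------------
# Kinetics track


class IpdTrack:
    """Dense per-position, per-strand kinetics observations.

    Positions are 1-based; each strand carries parallel arrays of IPD ratio,
    modification QV and coverage.  Missing observations are NaN.
    """

    COLUMNS = ["position", "strand", "ipd_ratio", "mod_qv", "coverage"]

    def __init__(self, length: int, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.length = length
        self._data = {}
        for strand in "+-":
            ipd, qv, cov = data[strand]
            if not (len(ipd) == len(qv) == len(cov) == length):
                raise ValueError("per-strand arrays must match the genome length")
            self._data[strand] = (
                np.asarray(ipd, dtype=float),
                np.asarray(qv, dtype=float),
                np.asarray(cov, dtype=float),
            )

    def ipd(self, strand: str) -> np.ndarray:
        return self._data[strand][0]

    def mod_qv(self, strand: str) -> np.ndarray:
        return self._data[strand][1]

    def coverage(self, strand: str) -> np.ndarray:
        return self._data[strand][2]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for strand in "+-":
            ipd, qv, cov = self._data[strand]
            frames.append(
                pd.DataFrame(
                    {
                        "position": np.arange(1, self.length + 1),
                        "strand": strand,
                        "ipd_ratio": ipd,
                        "mod_qv": qv,
                        "coverage": cov,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, length: int | None = None) -> "IpdTrack":
        if length is None:
            length = int(frame["position"].max())
        data = {}
        for strand in "+-":
            ipd = np.full(length, np.nan)
            qv = np.full(length, np.nan)
            cov = np.full(length, np.nan)
            sub = frame[frame["strand"] == strand]
            idx = sub["position"].to_numpy(dtype=int) - 1
            ipd[idx] = sub["ipd_ratio"].to_numpy(dtype=float)
            qv[idx] = sub["mod_qv"].to_numpy(dtype=float)
            cov[idx] = sub["coverage"].to_numpy(dtype=float)
            data[strand] = (ipd, qv, cov)
        return cls(length, data)

    @classmethod
    def read_tsv(cls, path: str | Path, length: int | None = None) -> "IpdTrack":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), length)


# ---------------------------------------------------------------------------
# Cytosine context classification


def _context_codes_one_strand(seq: str, circular: bool) -> np.ndarray:
    base = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    c_byte, g_byte = ord("C"), ord("G")

    def shifted(offset: int) -> np.ndarray:
        if circular:
            return np.roll(base, -offset)
        out = np.zeros_like(base)
        if offset > 0:
            out[:-offset] = base[offset:]
        elif offset < 0:
            out[-offset:] = base[:offset]
        else:
            out = base
        return out

    is_c = base == c_byte
    cgcg_first = (
        is_c
        & (shifted(1) == g_byte)
        & (shifted(2) == c_byte)
        & (shifted(3) == g_byte)
    )
    if circular:
        cgcg_second = np.roll(cgcg_first, 2) & is_c
    else:
        cgcg_second = np.zeros_like(cgcg_first)
        cgcg_second[2:] = cgcg_first[:-2]
        cgcg_second &= is_c
    cg = is_c & (shifted(1) == g_byte)
    codes = np.zeros(len(base), dtype=np.int8)
    codes[is_c] = _CODE["C_other"]
    codes[cg] = _CODE["CG_firstC"]
    codes[cgcg_second] = _CODE["CGCG_secondC"]
    codes[cgcg_first] = _CODE["CGCG_firstC"]
    return codes


def cytosine_context_codes(genome: GenomeRecord) -> dict[str, np.ndarray]:
    """Per-strand context codes indexed by 0-based genomic position.

    The minus-strand entry gives, at genomic index i, the context of that
    position as read 5'->3' on the reverse strand.
    """
    circular = genome.topology == "circular"
    plus = _context_codes_one_strand(genome.sequence, circular)
    minus = _context_codes_one_strand(reverse_complement(genome.sequence), circular)[::-1]
    return {"+": plus, "-": minus.copy()}


def context_mean_ipd(
    genome: GenomeRecord, track: IpdTrack, context: str
) -> tuple[int, float, float]:
    """(n, mean, sd) of IPD ratios over one cytosine context, both strands."""
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    codes = cytosine_context_codes(genome)
    values = []
    for strand in "+-":
        mask = codes[strand] == _CODE[context]
        values.append(track.ipd(strand)[mask])
    pooled = np.concatenate(values)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise EmptyContextError(f"no observations in context {context}")
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return int(pooled.size), float(pooled.mean()), sd


# ---------------------------------------------------------------------------
# Per-motif summaries


@dataclass(frozen=True)
class MotifSummary:
    motif: IupacMotif
    n_genome: int
    n_detected: int
    pct_detected: float | None
    mean_qv: float | None
    mean_coverage: float | None
    partner: str
    empty: bool = False


def modified_site_coordinates(
    genome: GenomeRecord, motif: IupacMotif
) -> list[tuple[int, str]]:
    """Genomic (position, strand) of the modified base of every motif site."""
    length = len(genome)
    offset = motif.modified_position - 1
    coords = []
    for pos, strand in scan_motif(genome, motif):
        if strand == "+":
            coord = pos + offset
        else:
            coord = pos - offset
        coords.append(((coord - 1) % length + 1, strand))
    return coords


def motif_summary(
    genome: GenomeRecord,
    motif: IupacMotif,
    track: IpdTrack,
    qv_threshold: float = 30.0,
) -> MotifSummary:
    """Detection roll-up over the modified base of every motif site."""
    partner = partner_motif(motif).pattern
    coords = modified_site_coordinates(genome, motif)
    if not coords:
        return MotifSummary(motif, 0, 0, None, None, None, partner, empty=True)
    qvs = np.array([track.mod_qv(strand)[pos - 1] for pos, strand in coords])
    covs = np.array([track.coverage(strand)[pos - 1] for pos, strand in coords])
    detected = qvs >= qv_threshold
    n_detected = int(np.nansum(detected))
    mean_qv = float(qvs[detected].mean()) if n_detected else None
    mean_cov = float(np.nanmean(covs)) if covs.size else None
    return MotifSummary(
        motif=motif,
        n_genome=len(coords),
        n_detected=n_detected,
        pct_detected=100.0 * n_detected / len(coords),
        mean_qv=mean_qv,
        mean_coverage=mean_cov,
        partner=partner,
    )


def overspecification_check(
    genome: GenomeRecord, motif: IupacMotif, min_count: int = 30
) -> tuple[int, bool]:
    """Flag motifs with fewer genomic sites than plausibly real recognition
    sequences have (a long, fully specified motif caller artifact)."""
    n_genome = len(scan_motif(genome, motif))
    return n_genome, n_genome < min_count


def methylome_report(
    genome: GenomeRecord,
    motifs: Sequence[IupacMotif],
    track: IpdTrack,
    qv_threshold: float = 30.0,
) -> pd.DataFrame:
    """Per-motif summary table (one row per given motif)."""
    rows = []
    for motif in motifs:
        summary = motif_summary(genome, motif, track, qv_threshold)
        rows.append(
            {
                "motif": motif.pattern,
                "modified_position": motif.modified_position,
                "type": motif.modification_type,
                "pct_detected": summary.pct_detected,
                "n_detected": summary.n_detected,
                "n_genome": summary.n_genome,
                "mean_qv": summary.mean_qv,
                "mean_coverage": summary.mean_coverage,
                "partner": summary.partner,
            }
        )
    return pd.DataFrame(rows)


def write_sites_bed(
    genome: GenomeRecord, motif: IupacMotif, path: str | Path
) -> None:
    """Motif sites as BED (0-based half-open, strand in column 6)."""
    plen = len(motif)
    rows = []
    for pos, strand in scan_motif(genome, motif):
        if strand == "+":
            start = pos - 1
        else:
            start = pos - plen
        rows.append((genome.id, start, start + plen, motif.pattern, ".", strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Welch heteroscedastic t-test from summary statistics


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_freedom: float
    p_two_sided: float
    group_stats: tuple[tuple[int, float, float], tuple[int, float, float]]
    degenerate: bool = False


def welch_t(
    a: tuple[int, float, float], b: tuple[int, float, float]
) -> WelchResult:
    """Two-sided Welch t-test from (n, mean, sd) summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); degrees of freedom by
    Welch-Satterthwaite; p from the t-distribution survival function.
    """
    (n1, m1, s1), (n2, m2, s2) = a, b
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    if v1 + v2 == 0.0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0, (a, b))
        sign = 1.0 if m1 > m2 else -1.0
        return WelchResult(
            sign * math.inf, float(n1 + n2 - 2), 0.0, (a, b), degenerate=True
        )
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p, (a, b))
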