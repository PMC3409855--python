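"""Promoter-based transcription-factor activity inference.

A transcription factor's activity is inferred from the differential
prevalence of its binding motif in the promoters of differentially
expressed genes versus background genes. Motifs are position-weight
matrices (PWMs); candidate sites are scored with the information-weighted
matrix-similarity score (``mat_sim``, MatInspector lineage):

    score(s) = Σ_i I_i · f_i(s_i)  /  Σ_i I_i · max_b f_i(b)

with per-position information weight ``I_i = ln4 + Σ_b f_i(b)·ln f_i(b)``
(0·ln0 ≡ 0). The score lies in [0, 1] and equals 1 exactly on a consensus
sequence. Site counts are accumulated over a grid of 3 promoter windows
(−300, −600, −1000 … +200 bp around the TSS) × 3 detection stringencies
(0.80, 0.90, 0.95), and the activity statistic is the mean, over those 9
combinations, of the target-vs-background fold-difference in sites per
promoter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr

__all__ = [
    "PWM",
    "ScanGrid",
    "PromoterRecord",
    "parse_transfac",
    "write_transfac",
    "pwm_from_counts",
    "pwm_from_consensus",
    "builtin_motifs",
    "mat_sim",
    "extract_window",
    "scan_count",
    "build_count_table",
    "tf_activity",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_LN4 = math.log(4.0)


@dataclass(frozen=True)
class PWM:
    """Position-weight matrix: per-position base frequencies and info weights."""

    name: str
    freqs: np.ndarray  # (L, 4), rows sum to 1

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError(f"{self.name}: frequency matrix must be L x 4")
        if f.shape[0] < 1:
            raise ValueError(f"{self.name}: empty matrix")
        if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1) > 1e-9):
            raise ValueError(f"{self.name}: each column of frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def info(self) -> np.ndarray:
        """Per-position information weight I_i = ln4 + Σ f ln f, >= 0."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            flogf = np.where(f > 0, f * np.log(f), 0.0)
        return np.clip(_LN4 + flogf.sum(axis=1), 0.0, None)

    @property
    def degenerate(self) -> bool:
        """All positions uninformative (uniform matrix)."""
        return bool(np.all(self.info <= 1e-12))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.freqs[::-1, ::-1])


def pwm_from_counts(name: str, counts) -> PWM:
    """Normalise a count matrix column-wise to frequencies (no pseudocount)."""
    c = np.asarray(counts, dtype=float)
    tot = c.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError(f"{name}: a position has zero total count")
    return PWM(name, c / tot)


def pwm_from_consensus(name: str, consensus: str, p_match: float = 0.91) -> PWM:
    """Sharp synthetic PWM concentrating `p_match` on each consensus base."""
    L = len(consensus)
    f = np.full((L, 4), (1 - p_match) / 3)
    for i, b in enumerate(consensus.upper()):
        f[i, _CODE[b]] = p_match
    return PWM(name, f)


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O


def parse_transfac(text: str) -> list[PWM]:
    """Parse PWMs from TRANSFAC flat format (NA name line, P0 count rows).

    Count rows are normalised column-wise to frequencies. A malformed count
    row (not 4 numeric fields) raises with its line number.
    """
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []

    def flush(lineno):
        nonlocal name, rows
        if rows:
            if name is None:
                raise ValueError(f"line {lineno}: matrix record has no NA/ID name")
            pwms.append(pwm_from_counts(name, np.array(rows)))
        name, rows = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line == "XX":
            continue
        tag = line.split(maxsplit=1)[0]
        if tag == "//":
            flush(lineno)
        elif tag in ("NA", "ID"):
            parts = line.split(maxsplit=1)
            if len(parts) == 2 and (name is None or tag == "NA"):
                name = parts[1].strip()
        elif tag == "P0" or tag == "PO":
            continue
        elif tag.isdigit():
            fields = line.split()
            vals = fields[1:5]
            try:
                row = [float(v) for v in vals]
            except ValueError:
                row = []
            if len(row) != 4:
                raise ValueError(
                    f"line {lineno}: malformed count row (need 4 numeric values): {raw!r}"
                )
            rows.append(row)
        # other tags (AC, DE, BF, CC...) are metadata; ignored
    flush(lineno if text else 0)
    return pwms


def write_transfac(pwms: list[PWM]) -> str:
    """Serialise PWMs to TRANSFAC flat format (frequencies written verbatim,
    so write → parse round-trips to identical matrices)."""
    out = []
    for pwm in pwms:
        out.append(f"NA  {pwm.name}")
        out.append("XX")
        out.append("P0      A       C       G       T")
        cons = pwm.consensus
        for i, row in enumerate(pwm.freqs, start=1):
            vals = "  ".join(repr(float(v)) for v in row)
            out.append(f"{i:02d}  {vals}  {cons[i - 1]}")
        out.append("XX")
        out.append("//")
    return "\n".join(out) + "\n"


def builtin_motifs(p_match: float = 0.91) -> list[PWM]:
    """Toy synthetic motif library standing in for user-supplied TRANSFAC files.

    Eight sharp consensus-based matrices named after the inflammatory and
    myeloid transcription-factor families commonly profiled in leukocyte
    promoter analyses. These are synthetic constructions, not database
    matrices; supply a real TRANSFAC file for production use.
    """
    consensi = {
        "NFKB_SYN": "GGGACTTTCC",
        "STAT1_SYN": "TTCCCGGAAA",
        "EGR1_SYN": "GCGTGGGCGG",
        "EGR2_SYN": "GCGGGGGCGG",
        "EGR3_SYN": "GCGCGGGGGA",
        "NGFIC_SYN": "GCGCATGCGC",
        "MEF2_SYN": "CTAAAAATAG",
        "MZF1_SYN": "GGGGAGGGGA",
    }
    return [pwm_from_consensus(n, c, p_match) for n, c in consensi.items()]


# ---------------------------------------------------------------------------
# Scoring and scanning


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)  # 4 = ambiguous
    for b, i in _CODE.items():
        table[ord(b)] = i
    return table[codes]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, 4).astype(np.int8)
    return out[::-1]


def _score_table(pwm: PWM, ambiguous: str) -> tuple[np.ndarray, float]:
    info = pwm.info
    W = info[:, None] * pwm.freqs  # (L, 4)
    if ambiguous == "expect":
        amb = info * 0.25  # expected f under a uniform base
    elif ambiguous == "skip":
        amb = np.full(pwm.width, np.nan)
    else:
        raise ValueError(f"unknown ambiguous-base policy: {ambiguous!r}")
    W = np.column_stack([W, amb])
    denom = float((info * pwm.freqs.max(axis=1)).sum())
    return W, denom


def mat_sim(pwm: PWM, subseq: str, ambiguous: str = "expect") -> float:
    """Information-weighted matrix-similarity score of one candidate site.

    1.0 on a consensus; a degenerate (uniform) matrix scores 1.0 for any
    sequence by convention (check ``pwm.degenerate``). With the ``"skip"``
    ambiguity policy a site containing an ambiguous base returns NaN.
    """
    if len(subseq) != pwm.width:
        raise ValueError(f"site length {len(subseq)} != matrix width {pwm.width}")
    W, denom = _score_table(pwm, ambiguous)
    if denom <= 0:
        return 1.0
    codes = _encode(subseq)
    s = float(W[np.arange(pwm.width), codes].sum())
    return s / denom


def _offset_scores(pwm: PWM, codes: np.ndarray, ambiguous: str) -> np.ndarray:
    """mat_sim at every offset of one strand; empty if sequence shorter than L."""
    L = pwm.width
    n = codes.size
    if n < L:
        return np.empty(0)
    W, denom = _score_table(pwm, ambiguous)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    contrib = W[np.arange(L)[None, :], windows]  # (n-L+1, L)
    if denom <= 0:
        return np.ones(n - L + 1)
    return contrib.sum(axis=1) / denom


def scan_count(
    pwm: PWM, sequence: str, stringency: float, ambiguous: str = "expect"
) -> int:
    """Count motif sites at or above `stringency` on both strands.

    The matrix and its reverse complement slide over every offset;
    overlapping hits all count. A sequence shorter than the matrix yields 0.
    """
    if not 0 < stringency <= 1:
        raise ValueError("stringency must lie in (0, 1]")
    codes = _encode(sequence)
    total = 0
    for strand in (codes, _revcomp_codes(codes)):
        s = _offset_scores(pwm, strand, ambiguous)
        total += int(np.count_nonzero(s >= stringency))
    return total


# ---------------------------------------------------------------------------
# Promoter windows and the scan grid


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    sequence: str
    tss_offset: int  # 0-based index of the first transcribed base


@dataclass(frozen=True)
class ScanGrid:
    """3 promoter windows × 3 stringencies = 9 combinations."""

    upstreams: tuple[int, ...] = (300, 600, 1000)
    downstream: int = 200
    stringencies: tuple[float, ...] = (0.80, 0.90, 0.95)

    @property
    def combinations(self):
        return [(u, s) for u in self.upstreams for s in self.stringencies]


def extract_window(record: PromoterRecord, upstream: int, downstream: int = 200) -> str:
    """Half-open slice [TSS − upstream, TSS + downstream) of the promoter.

    Windows extending past the record are truncated with a warning (the
    counted length is whatever remains).
    """
    start = record.tss_offset - upstream
    end = record.tss_offset + downstream
    n = len(record.sequence)
    if start < 0 or end > n:
        warnings.warn(
            f"{record.gene_id}: window ({-upstream},+{downstream}) exceeds the "
            f"record; truncated to {max(start, 0)}..{min(end, n)}"
        )
    return record.sequence[max(start, 0) : min(end, n)]


def build_count_table(
    promoters: list[PromoterRecord],
    pwms: list[PWM],
    grid: ScanGrid = ScanGrid(),
    ambiguous: str = "expect",
) -> pd.DataFrame:
    """Exhaustive site counts over genes × motifs × the window/stringency grid.

    Long-format table with columns gene, motif, upstream, stringency, count.
    Deterministic; one score pass per (gene, motif, window, strand) serves
    all stringencies.
    """
    rows = []
    for rec in promoters:
        for up in grid.upstreams:
            seq = extract_window(rec, up, grid.downstream)
            codes = _encode(seq)
            rc = _revcomp_codes(codes)
            for pwm in pwms:
                s_f = _offset_scores(pwm, codes, ambiguous)
                s_r = _offset_scores(pwm, rc, ambiguous)
                for sg in grid.stringencies:
                    count = int(np.count_nonzero(s_f >= sg)) + int(
                        np.count_nonzero(s_r >= sg)
                    )
                    rows.append((rec.gene_id, pwm.name, up, sg, count))
    return pd.DataFrame(
        rows, columns=["gene", "motif", "upstream", "stringency", "count"]
    )


def tf_activity(
    table: pd.DataFrame,
    target_genes,
    background_genes,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mean fold-difference in sites per promoter, target vs background.

    For each motif and each of the 9 grid combinations the fold is the ratio
    of mean sites per promoter. A small symmetric density offset,
    ``pseudocount · (1/n_target + 1/n_background) / 2`` (about half a site
    spread over each group), is added to both means so an all-zero
    combination yields fold 1 instead of dividing by zero, while calibrated
    ratios are left essentially unchanged. Reported per motif: the 9 folds'
    mean and SE, a two-sided one-sample t-test of the 9 log folds against 0
    (df 8), and BH q-values across motifs.
    """
    target = [g for g in target_genes]
    background = [g for g in background_genes]
    if not target or not background:
        raise ValueError("target and background gene sets must be nonempty")
    if set(target) & set(background):
        raise ValueError("target and background gene sets must be disjoint")
    present = set(table["gene"].unique())
    t_in = [g for g in target if g in present]
    b_in = [g for g in background if g in present]
    if len(t_in) < len(target) or len(b_in) < len(background):
        warnings.warn(
            f"dropping genes without promoter counts: "
            f"{len(target) - len(t_in)} target, {len(background) - len(b_in)} background"
        )
    if not t_in or not b_in:
        raise ValueError("no target or background genes present in the count table")

    piv = table.pivot_table(
        index="gene", columns=["motif", "upstream", "stringency"], values="count"
    )
    t_mean = piv.loc[t_in].sum(axis=0) / len(t_in)
    b_mean = piv.loc[b_in].sum(axis=0) / len(b_in)
    eps = pseudocount * (1.0 / len(t_in) + 1.0 / len(b_in)) / 2.0
    fold = (t_mean + eps) / (b_mean + eps)

    rows = []
    for motif in fold.index.get_level_values("motif").unique():
        f9 = fold.loc[motif].to_numpy(dtype=float)
        logf = np.log(f9)
        mean_fold = float(f9.mean())
        se = float(f9.std(ddof=1) / np.sqrt(f9.size)) if f9.size > 1 else 0.0
        if f9.size > 1 and logf.std(ddof=1) > 0:
            p = float(stats.ttest_1samp(logf, 0.0).pvalue)
        else:
            p = 1.0
        rows.append(
            {
                "motif": motif,
                "mean_fold": mean_fold,
                "se_fold": se,
                "n_combinations": int(f9.size),
                "p": p,
                "folds": list(f9),
            }
        )
    res = pd.DataFrame(rows).set_index("motif")
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res
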