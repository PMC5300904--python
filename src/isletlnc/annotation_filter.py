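"""Candidate-retention filters for de novo beta-cell lncRNA annotation.

Transcripts assembled from islet RNA-seq are kept as beta-cell lncRNA
candidates only when three independent lines of evidence agree: detectable
expression in FACS-purified beta cells, no enrichment in the pancreatic
exocrine fraction (which would point to acinar contamination), and an
H3K4me3 promoter mark near the transcript's 5' end.  The numeric cutoffs
are configuration parameters with documented defaults, not measured
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TranscriptCandidate", "filter_candidates", "tss_peak_distances"]


@dataclass
class TranscriptCandidate:
    """One assembled transcript with the evidence used by the filters.

    beta_expression: abundance in purified beta cells (arbitrary units).
    exocrine_ratio: exocrine / islet abundance ratio.
    tss_h3k4me3_distance: bp from the 5' end to the nearest H3K4me3 peak,
    or None when no peak was found.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    beta_expression: float | None = None
    exocrine_ratio: float | None = None
    tss_h3k4me3_distance: int | None = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def filter_candidates(
    candidates: list[TranscriptCandidate],
    min_beta_expr: float = 0.5,
    max_exocrine_ratio: float = 1.0,
    max_h3k4me3_distance: int = 2000,
) -> tuple[list[TranscriptCandidate], dict[str, str]]:
    """Apply the three retention rules in order; report the first failure.

    A candidate is retained iff beta_expression >= min_beta_expr AND
    exocrine_ratio <= max_exocrine_ratio AND a H3K4me3 peak lies within
    max_h3k4me3_distance of the 5' end.  Records with missing fields are
    rejected as incomplete (a missing peak distance fails the promoter
    rule instead, since "no peak nearby" is an observation).  Returns
    (retained in input order, rejection reason per rejected id).
    """
    if min_beta_expr <= 0 or max_exocrine_ratio <= 0 or max_h3k4me3_distance <= 0:
        raise ValueError("thresholds must be positive")
    retained: list[TranscriptCandidate] = []
    reasons: dict[str, str] = {}
    for cand in candidates:
        if cand.beta_expression is None or cand.exocrine_ratio is None:
            reasons[cand.id] = "incomplete record"
        elif cand.beta_expression < min_beta_expr:
            reasons[cand.id] = "below beta-cell expression threshold"
        elif cand.exocrine_ratio > max_exocrine_ratio:
            reasons[cand.id] = "exocrine-enriched"
        elif cand.tss_h3k4me3_distance is None:
            reasons[cand.id] = "no H3K4me3 peak near 5' end"
        elif cand.tss_h3k4me3_distance > max_h3k4me3_distance:
            reasons[cand.id] = "H3K4me3 peak too distant"
        else:
            retained.append(cand)
    return retained, reasons


def tss_peak_distances(
    candidates: list[TranscriptCandidate],
    peaks: pd.DataFrame,
) -> list[TranscriptCandidate]:
    """Fill tss_h3k4me3_distance from a peak table (chrom, start, end).

    Distance is from the candidate's 5' end to the nearest point of any
    peak on the same chromosome (0 when the TSS falls inside a peak);
    None when the chromosome has no peaks.
    """
    out = []
    for cand in candidates:
        chrom_peaks = peaks[peaks["chrom"] == cand.chrom]
        if chrom_peaks.empty:
            dist = None
        else:
            tss = cand.tss
            d = [0 if s <= tss < e else min(abs(tss - s), abs(tss - (e - 1)))
                 for s, e in zip(chrom_peaks["start"], chrom_peaks["end"])]
            dist = int(min(d))
        out.append(TranscriptCandidate(**{**cand.__dict__, "tss_h3k4me3_distance": dist}))
    return out
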