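"""Published benchmark fixtures for validating the quantification pipeline.

Bundled plain-data records from a published clinical evaluation of
ensemble-based skeletal-muscle segmentation against expert manual reference
(SliceOmatic) across gastroesophageal, colorectal, pancreatic and ovarian CT
cohorts. They serve as frozen inputs for the summary-statistics,
agreement-identity and triage-reconstruction checks; nothing in this module
is computed by this package.

``GASTRO_TEST_AGREEMENT`` holds the 25 per-image agreement rows of the
gastroesophageal held-out test set, for both the deep-ensemble and the
Monte-Carlo-dropout variant of the segmenter: signed SMA percent difference
vs. the manual reference, Jaccard and Dice (percent), and false-positive /
false-negative pixel counts. ``OOD_CASE_IDS`` marks the four noisy /
out-of-distribution images in that set.

``TRIAGE_COUNTS`` holds, for each published triage operating point
(cohort × uncertainty metric × threshold), the above/below-threshold case
counts and how many of each were misclassified: ``fp`` low-error cases above
the threshold, ``fn`` high-error cases below it (high error means >2.5% SMA
difference from the manual reference).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AgreementRow",
    "GASTRO_TEST_AGREEMENT",
    "OOD_CASE_IDS",
    "TriageCountRecord",
    "TRIAGE_COUNTS",
    "WORKED_PIXEL_COUNTS",
    "triage_vectors",
]


@dataclass(frozen=True)
class AgreementRow:
    case_id: str
    ens_diff: float  # signed SMA difference %, ensemble
    ens_jaccard: float
    ens_dice: float
    ens_fp: int
    ens_fn: int
    drop_diff: float  # same, dropout variant
    drop_jaccard: float
    drop_dice: float
    drop_fp: int
    drop_fn: int


GASTRO_TEST_AGREEMENT: tuple[AgreementRow, ...] = tuple(
    AgreementRow(*row)
    for row in [
        ("2.2", 0.89, 97.39, 98.68, 381, 189, 0.586, 97.64, 98.81, 320, 194),
        ("2.4", -0.16, 96.98, 98.47, 262, 291, 2.360, 95.44, 97.67, 639, 213),
        ("3.1", 0.79, 94.14, 96.98, 701, 539, -1.056, 91.45, 95.54, 800, 1016),
        ("4.1", 0.17, 98.98, 99.49, 119, 86, 0.240, 98.96, 99.48, 129, 81),
        ("4.2", 1.67, 97.04, 98.50, 505, 147, 2.149, 96.86, 98.41, 577, 115),
        ("5.1", -1.13, 94.52, 97.18, 298, 448, -1.277, 94.61, 97.23, 281, 451),
        ("5.2", -0.76, 95.10, 97.49, 272, 369, -0.820, 95.72, 97.82, 226, 331),
        ("5.3", -0.75, 94.54, 97.19, 374, 489, -0.052, 94.21, 97.02, 456, 464),
        ("5.4", -0.37, 94.59, 97.22, 429, 490, 0.272, 93.08, 96.42, 617, 572),
        ("7.3", 5.17, 86.69, 92.87, 2916, 1393, 6.251, 86.56, 92.80, 3108, 1267),
        ("9.1", -0.66, 97.28, 98.62, 197, 323, -1.451, 97.41, 98.69, 109, 384),
        ("9.2", 1.95, 95.01, 97.44, 669, 302, 2.288, 94.93, 97.40, 709, 279),
        ("9.3", 11.14, 86.11, 92.53, 3041, 523, 12.427, 84.90, 91.83, 3366, 556),
        ("15.1", 5.87, 92.58, 96.14, 488, 73, 5.504, 93.33, 96.55, 445, 56),
        ("15.2", 0.83, 98.26, 99.12, 259, 93, 0.496, 98.33, 99.16, 218, 119),
        ("15.3", -1.97, 96.90, 98.42, 106, 471, -1.881, 96.73, 98.34, 131, 479),
        ("15.4", 2.64, 92.34, 96.02, 1100, 557, 2.757, 92.86, 96.30, 1054, 488),
        ("15.5", -0.81, 92.98, 96.36, 701, 877, 0.597, 93.36, 96.56, 815, 685),
        ("16.1", -0.18, 97.94, 98.96, 172, 205, -0.320, 97.85, 98.91, 168, 226),
        ("16.2", 1.54, 94.12, 96.97, 729, 436, 1.799, 93.88, 96.84, 779, 436),
        ("16.3", -0.80, 96.21, 98.07, 238, 363, -0.436, 96.22, 98.07, 266, 334),
        ("21.1", 0.52, 96.85, 98.40, 125, 90, 0.328, 97.27, 98.62, 104, 82),
        ("21.3", -0.24, 94.84, 97.35, 481, 527, -0.173, 94.93, 97.40, 479, 512),
        ("21.5", -0.10, 93.99, 96.90, 612, 612, 0.015, 94.21, 97.02, 582, 579),
        ("23.2", 19.85, 79.75, 88.73, 4170, 460, 22.56, 78.11, 87.71, 4665, 448),
    ]
)

#: Noisy / out-of-distribution cases excluded from the in-distribution summary.
OOD_CASE_IDS: frozenset[str] = frozenset({"7.3", "9.3", "15.1", "23.2"})


@dataclass(frozen=True)
class TriageCountRecord:
    """Above/below-threshold case counts at one published operating point."""

    cohort: str
    metric: str  # "avg_variance" or "cov_sma"
    threshold: float
    n_above: int  # flagged cases
    fp: int  # low-error cases above the threshold
    n_below: int
    fn: int  # high-error cases below the threshold

    @property
    def n(self) -> int:
        return self.n_above + self.n_below


TRIAGE_COUNTS: tuple[TriageCountRecord, ...] = (
    TriageCountRecord("gastroesophageal", "cov_sma", 2.00, 5, 1, 20, 1),
    TriageCountRecord("gastroesophageal", "avg_variance", 0.50, 7, 3, 18, 1),
    TriageCountRecord("colorectal", "avg_variance", 0.12, 36, 14, 17, 9),
    TriageCountRecord("colorectal", "avg_variance", 0.20, 18, 6, 35, 19),
    TriageCountRecord("colorectal", "cov_sma", 0.30, 36, 13, 17, 8),
    TriageCountRecord("colorectal", "cov_sma", 0.50, 23, 9, 30, 17),
    TriageCountRecord("pancreatic", "avg_variance", 0.20, 53, 30, 56, 12),
    TriageCountRecord("pancreatic", "avg_variance", 0.40, 16, 7, 93, 27),
    TriageCountRecord("pancreatic", "cov_sma", 0.60, 54, 32, 55, 13),
    TriageCountRecord("pancreatic", "cov_sma", 1.00, 32, 17, 77, 20),
    TriageCountRecord("ovarian", "avg_variance", 0.35, 102, 12, 52, 23),
    TriageCountRecord("ovarian", "avg_variance", 0.60, 56, 4, 98, 62),
    TriageCountRecord("ovarian", "cov_sma", 1.00, 109, 17, 45, 20),
    TriageCountRecord("ovarian", "cov_sma", 1.50, 71, 7, 83, 48),
)

#: Worked examples of noisy gastroesophageal cases: (automated pixel count,
#: manual-reference pixel count) for two slices.
WORKED_PIXEL_COUNTS: tuple[tuple[int, int], ...] = ((22404, 18694), (30976, 29453))


def triage_vectors(rec: TriageCountRecord) -> tuple[list[float], list[float]]:
    """Expand a triage count record into per-case (uncertainty, |error|) vectors.

    Flagged cases get an uncertainty strictly above the published threshold,
    unflagged cases one strictly below; high-error cases get |error| 10%,
    low-error cases 1%. Feeding these vectors through
    :func:`musclequant.triage.evaluate` at the published threshold must
    reproduce the published operating point exactly.
    """
    u: list[float] = []
    e: list[float] = []
    tp = rec.n_above - rec.fp
    tn = rec.n_below - rec.fn
    above_u = rec.threshold * 1.25 + 0.01
    below_u = rec.threshold * 0.75
    for count, unc, err in (
        (tp, above_u, 10.0),
        (rec.fp, above_u, 1.0),
        (rec.fn, below_u, 10.0),
        (tn, below_u, 1.0),
    ):
        u.extend([unc] * count)
        e.extend([err] * count)
    return u, e
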