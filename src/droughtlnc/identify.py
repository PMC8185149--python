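"""lncRNA identification: candidate filtering, positional classification,
coding-potential scoring and the all-predictor consensus call.

Candidates must (1) exceed 200 bp with at least 2 exons, (2) carry at
least 5 reads of support, (3) not match known mRNA/ncRNA IDs, and
(4) belong to one of the positional class codes "u" (intergenic),
"i" (intronic) or "x" (antisense).  Survivors are scored for coding
potential; a transcript is called lncRNA only when every supplied
predictor labels it noncoding (consensus by intersection).

External predictor outputs (CNCI/CPC/CPAT/Pfam-scan style) enter as
two-column label TSVs; a built-in stand-in scorer combining maximum ORF
length, the Fickett TESTCODE statistic and a hexamer log-likelihood
ratio is provided so the pipeline runs self-contained.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, Transcript, ValidationError

FILTER_RULES = ("length", "exons", "reads", "known", "class_code")

#: class code -> positional class name
POSITIONAL_CLASS = {"u": "lincRNA", "i": "intronic", "x": "antisense"}

_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterResult:
    """One candidate with its per-rule verdicts."""

    transcript: Transcript
    flags: dict[str, bool]  # rule -> passed?

    @property
    def passed(self) -> bool:
        return all(self.flags.values())


def filter_candidates(
    transcripts: Sequence[Transcript],
    counts: ExpressionMatrix,
    known_ids: set[str],
    min_length: int = 200,
    min_exons: int = 2,
    min_reads: int = 5,
    read_mode: str = "total",
) -> list[FilterResult]:
    """Apply the four candidate filters, recording each rule's verdict.

    ``read_mode`` is "total" (>= min_reads summed over all samples, the
    default reading) or "every_sample" (>= min_reads in each sample, the
    stricter alternative).  Length must be strictly above ``min_length``;
    exon count at least ``min_exons``.
    """
    if read_mode not in {"total", "every_sample"}:
        raise ValidationError(f"unknown read_mode {read_mode!r}")
    missing = [
        t.transcript_id for t in transcripts if t.transcript_id not in counts.data.index
    ]
    if missing:
        raise ValidationError(
            "transcripts absent from count matrix: " + ", ".join(missing[:10])
        )
    out = []
    for t in transcripts:
        row = counts.data.loc[t.transcript_id]
        if read_mode == "total":
            reads_ok = int(row.sum()) >= min_reads
        else:
            reads_ok = bool((row >= min_reads).all())
        flags = {
            "length": t.length > min_length,
            "exons": t.n_exons >= min_exons,
            "reads": reads_ok,
            "known": t.transcript_id not in known_ids,
            "class_code": t.class_code in POSITIONAL_CLASS,
        }
        out.append(FilterResult(t, flags))
    return out


# ---------------------------------------------------------------------------
# classification and consensus


@dataclass
class CodingLabelSet:
    """One predictor's verdicts: transcript_id -> "coding" | "noncoding"."""

    predictor_name: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"coding", "noncoding"}
        if bad:
            raise ValidationError(
                f"{self.predictor_name}: labels must be coding/noncoding, got {bad}"
            )


@dataclass
class LncRNACall:
    transcript_id: str
    positional_class: str
    predictor_labels: dict[str, str] = field(default_factory=dict)
    consensus_noncoding: bool | None = None


class LncRNASet:
    """Classified candidates with per-predictor labels and consensus."""

    def __init__(self, calls: Iterable[LncRNACall]):
        self.calls: dict[str, LncRNACall] = {c.transcript_id: c for c in calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls.values())

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(c.positional_class for c in self))

    def consensus_ids(self) -> list[str]:
        return [c.transcript_id for c in self if c.consensus_noncoding]

    def to_frame(self) -> pd.DataFrame:
        if not self.calls:
            return pd.DataFrame(
                columns=["transcript_id", "positional_class", "consensus_noncoding"]
            ).set_index("transcript_id")
        predictors = sorted({p for c in self for p in c.predictor_labels})
        rows = []
        for c in self.calls.values():
            row = {
                "transcript_id": c.transcript_id,
                "positional_class": c.positional_class,
            }
            for p in predictors:
                row[f"label_{p}"] = c.predictor_labels.get(p, "NA")
            row["consensus_noncoding"] = c.consensus_noncoding
            rows.append(row)
        return pd.DataFrame(rows).set_index("transcript_id")


def classify_by_class_code(candidates: Sequence[Transcript]) -> LncRNASet:
    """Map class codes to positional classes: u -> lincRNA, i -> intronic,
    x -> antisense.  Any other code here means the filter contract was
    broken upstream."""
    calls = []
    for t in candidates:
        if t.class_code not in POSITIONAL_CLASS:
            raise ValidationError(
                f"{t.transcript_id}: class code {t.class_code!r} reached "
                "classification; candidates must be filtered first"
            )
        calls.append(LncRNACall(t.transcript_id, POSITIONAL_CLASS[t.class_code]))
    return LncRNASet(calls)


def consensus_noncoding(
    lncrna_set: LncRNASet, label_sets: Sequence[CodingLabelSet]
) -> LncRNASet:
    """AND over all predictors: noncoding only if every supplied predictor
    says noncoding.  A transcript missing from a label set is treated as
    coding (conservative) with a warning."""
    import warnings

    if not label_sets:
        raise ValidationError("need at least one predictor label set")
    for call in lncrna_set:
        verdicts = []
        for ls in label_sets:
            if call.transcript_id not in ls.labels:
                warnings.warn(
                    f"{call.transcript_id} missing from predictor "
                    f"{ls.predictor_name}; treated as coding"
                )
                label = "coding"
            else:
                label = ls.labels[call.transcript_id]
            call.predictor_labels[ls.predictor_name] = label
            verdicts.append(label == "noncoding")
        call.consensus_noncoding = all(verdicts)
    return lncrna_set


def predictor_tally(lncrna_set: LncRNASet) -> dict[str, int]:
    """Per-predictor noncoding counts (the per-tool tallies of the study's
    reporting), plus the consensus intersection size."""
    tally: Counter = Counter()
    for call in lncrna_set:
        for pred, label in call.predictor_labels.items():
            if label == "noncoding":
                tally[pred] += 1
    tally["consensus"] = sum(1 for c in lncrna_set if c.consensus_noncoding)
    return dict(tally)


def read_label_tsv(path: str | Path, predictor_name: str | None = None) -> CodingLabelSet:
    """Two-column TSV (transcript_id, coding|noncoding), so real external
    predictor runs can be dropped in unchanged."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "label"])
    return CodingLabelSet(
        predictor_name or path.stem,
        dict(zip(df["transcript_id"].astype(str), df["label"].astype(str))),
    )


# ---------------------------------------------------------------------------
# built-in coding-potential stand-in


def _check_sequence(name: str, seq: str) -> str:
    if not seq:
        raise ValidationError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"{name}: non-ACGTN characters {sorted(bad)}")
    return seq


def max_orf_codons(seq: str) -> int:
    """Longest open reading frame over the 3 forward frames, in codons
    counted from ATG up to (not including) the stop; an ORF running off
    the 3' end counts its readable codons."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        i = frame
        start = None
        n = len(seq)
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
            i += 3
        if start is not None:
            best = max(best, (len(seq) - start) // 3)
    return best


def _max_orf_region(seq: str) -> str:
    """The subsequence of the longest forward ORF (frame 0 whole sequence
    when no ATG-initiated ORF exists)."""
    seq = seq.upper()
    best = (0, 0, 0)  # codons, start, end
    for frame in range(3):
        i = frame
        start = None
        n = len(seq)
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                ln = (i - start) // 3
                if ln > best[0]:
                    best = (ln, start, i)
                start = None
            i += 3
        if start is not None:
            ln = (n - start) // 3
            if ln > best[0]:
                best = (ln, start, start + 3 * ln)
    if best[0] == 0:
        return seq
    return seq[best[1] : best[2]]


# Fickett (1982) TESTCODE lookup tables, the canonical constants used by
# coding-potential tools.  Probability rows run from the highest parameter
# bin down to the lowest.
_FICKETT_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_POSITION_BINS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_FICKETT_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_FICKETT_CONTENT_BINS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, bins: list[float], probs: list[float]) -> float:
    for b, p in zip(bins, probs):
        if value >= b:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic: weighted sum of base-position asymmetry
    and base-content probabilities.  Higher means more coding-like; the
    classical decision regions call > 0.95 coding."""
    seq = _check_sequence("fickett", seq)
    score = 0.0
    for base in "ACGT":
        pos_counts = [seq[off::3].count(base) for off in range(3)]
        position = max(pos_counts) / (min(pos_counts) + 1.0)
        content = seq.count(base) / len(seq)
        score += (
            _lookup(position, _FICKETT_POSITION_BINS, _FICKETT_POSITION_PROB[base])
            * _FICKETT_POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content, _FICKETT_CONTENT_BINS, _FICKETT_CONTENT_PROB[base])
            * _FICKETT_CONTENT_WEIGHT[base]
        )
    return score


def _hexamer_counts(seq: str, in_frame: bool) -> Counter:
    step = 3 if in_frame else 1
    counts: Counter = Counter()
    for i in range(0, len(seq) - 5, step):
        hexamer = seq[i : i + 6]
        if set(hexamer) <= set("ACGT"):
            counts[hexamer] += 1
    return counts


def train_hexamer_tables(
    sequences: Mapping[str, str], orf_min_codons: int = 100
) -> tuple[dict[str, float], dict[str, float]]:
    """Hexamer frequency tables trained from the input itself: coding
    usage from in-frame hexamers of long-ORF sequences, background from
    the remaining sequences.  Add-one smoothing over the 4096 hexamers."""
    coding: Counter = Counter()
    background: Counter = Counter()
    for name, seq in sequences.items():
        seq = _check_sequence(name, seq)
        if max_orf_codons(seq) >= orf_min_codons:
            coding.update(_hexamer_counts(_max_orf_region(seq), in_frame=True))
        else:
            background.update(_hexamer_counts(seq, in_frame=False))
    hexamers = ["".join(h) for h in itertools.product("ACGT", repeat=6)]
    c_tot = sum(coding.values()) + len(hexamers)
    b_tot = sum(background.values()) + len(hexamers)
    c_tab = {h: (coding[h] + 1) / c_tot for h in hexamers}
    b_tab = {h: (background[h] + 1) / b_tot for h in hexamers}
    return c_tab, b_tab


def hexamer_llr(
    seq: str, coding_table: Mapping[str, float], background_table: Mapping[str, float]
) -> float:
    """Mean in-frame hexamer log-likelihood ratio over the max-ORF region;
    positive means coding-like usage."""
    region = _max_orf_region(_check_sequence("hexamer", seq))
    counts = _hexamer_counts(region, in_frame=True)
    n = sum(counts.values())
    if n == 0:
        return 0.0
    total = 0.0
    for h, k in counts.items():
        total += k * np.log(coding_table[h] / background_table[h])
    return total / n


def score_coding_potential(
    sequences: Mapping[str, str],
    orf_min_codons: int = 100,
    fickett_cut: float = 0.95,
    hexamer_cut: float = 0.0,
    per_component: bool = False,
) -> CodingLabelSet | list[CodingLabelSet]:
    """Built-in stand-in for the external coding-potential predictors.

    Combined call: coding iff the longest forward ORF reaches
    ``orf_min_codons``, or both composition scores agree it is coding-like
    (Fickett >= ``fickett_cut`` and hexamer LLR > ``hexamer_cut``).  With
    ``per_component=True`` the three components are returned as separate
    label sets so the consensus machinery can be exercised the way the
    four external tools would feed it.
    """
    c_tab, b_tab = train_hexamer_tables(sequences, orf_min_codons)
    orf_labels: dict[str, str] = {}
    fickett_labels: dict[str, str] = {}
    hex_labels: dict[str, str] = {}
    combined: dict[str, str] = {}
    for name, seq in sequences.items():
        seq = _check_sequence(name, seq)
        orf = max_orf_codons(seq)
        fick = fickett_score(seq)
        llr = hexamer_llr(seq, c_tab, b_tab)
        orf_labels[name] = "coding" if orf >= orf_min_codons else "noncoding"
        fickett_labels[name] = "coding" if fick >= fickett_cut else "noncoding"
        hex_labels[name] = "coding" if llr > hexamer_cut else "noncoding"
        is_coding = orf >= orf_min_codons or (fick >= fickett_cut and llr > hexamer_cut)
        combined[name] = "coding" if is_coding else "noncoding"
    if per_component:
        return [
            CodingLabelSet("orf", orf_labels),
            CodingLabelSet("fickett", fickett_labels),
            CodingLabelSet("hexamer", hex_labels),
        ]
    return CodingLabelSet("builtin", combined)
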