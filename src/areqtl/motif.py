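"""ARE (NRF2 binding site) position-weight-matrix scanning and SNP scoring.

A PWM is built from aligned training sites as log2(frequency / background)
with a pseudocount; sequences are scanned on both strands, sites are called
above a fraction of the maximum attainable score, and SNP alleles are scored
by the change they induce in the best window overlapping the variant
(predicted gain or loss of NRF2 binding).

Coordinates are 0-based half-open throughout; minus-strand hits are reported
in plus-strand coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import InputError

__all__ = [
    "Pwm",
    "MotifHit",
    "SnpDelta",
    "build_pwm",
    "scan",
    "call_sites",
    "snp_allele_delta",
    "prioritize_snps",
    "hits_to_bed",
]

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position-specific log2-odds over A,C,G,T.

    ``matrix`` has shape (width, 4) in alphabet order ACGT; entries are
    log2(freq / background) and must be finite (pseudocount > 0 guarantees
    this at construction).
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise InputError("PWM matrix must be (width, 4)")
        if not np.isfinite(self.matrix).all():
            raise InputError("PWM entries must be finite (use pseudocount > 0)")
        if not np.isclose(self.background.sum(), 1.0):
            raise InputError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def score_word(self, word: str) -> float:
        if len(word) != self.width:
            raise InputError("word length must equal PWM width")
        return float(sum(self.matrix[j, _IDX[b]] for j, b in enumerate(word)))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "alphabet": ALPHABET,
                "matrix": self.matrix.tolist(),
                "background": self.background.tolist(),
                "pseudocount": self.pseudocount,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, path_or_text) -> "Pwm":
        try:
            d = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                d = json.load(fh)
        return cls(np.array(d["matrix"]), np.array(d["background"]), d["pseudocount"])


@dataclass
class MotifHit:
    seq_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    score: float
    score_fraction: float


@dataclass
class SnpDelta:
    snp_id: str
    seq_id: str
    offset: int
    ref: str
    alt: str
    ref_score: float
    alt_score: float
    delta: float
    inside_site: bool


def build_pwm(sites: list[str], pseudocount: float = 0.25,
              background=None) -> Pwm:
    """Build a log2-odds PWM from aligned, equal-length ACGT sites."""
    if len(sites) < 2:
        raise InputError("need at least 2 training sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise InputError("training sites must have equal lengths")
    sites = [s.upper() for s in sites]
    if any(b not in _IDX for s in sites for b in s):
        raise InputError("training sites must be over A,C,G,T")
    if pseudocount <= 0:
        raise InputError("pseudocount must be > 0 (absent bases otherwise give "
                         "infinite log-odds)")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for s in sites:
        for j, b in enumerate(s):
            counts[j, _IDX[b]] += 1
    freqs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return Pwm(np.log2(freqs / bg), bg, pseudocount)


def scan(pwm: Pwm, seq: str, seq_id: str = "seq") -> pd.DataFrame:
    """Score every window on both strands.

    Returns a DataFrame with columns seq_id, start, end, strand, score,
    score_fraction; positions are plus-strand 0-based half-open.  Windows
    containing a non-ACGT base are skipped (logged once per sequence).
    """
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w:
        raise InputError("sequence shorter than PWM width")
    codes = np.fromiter((_IDX.get(b, -1) for b in seq), dtype=np.int64, count=len(seq))
    nwin = len(seq) - w + 1
    idx = np.arange(nwin)[:, None] + np.arange(w)[None, :]
    win = codes[idx]  # (nwin, w)
    valid = (win >= 0).all(axis=1)
    if not valid.all():
        log.warning("%s: skipped %d windows containing ambiguous bases",
                    seq_id, int((~valid).sum()))
    safe = np.where(win >= 0, win, 0)
    fwd = pwm.matrix[np.arange(w)[None, :], safe].sum(axis=1)
    # minus strand: score the reverse complement of each window
    rc = 3 - safe[:, ::-1]
    rev = pwm.matrix[np.arange(w)[None, :], rc].sum(axis=1)
    rows = []
    for strand, sc in (("+", fwd), ("-", rev)):
        rows.append(pd.DataFrame({
            "seq_id": seq_id,
            "start": np.arange(nwin)[valid],
            "end": np.arange(nwin)[valid] + w,
            "strand": strand,
            "score": sc[valid],
        }))
    out = pd.concat(rows, ignore_index=True)
    out["score_fraction"] = out["score"] / pwm.max_score
    return out


def call_sites(scores: pd.DataFrame, pwm: Pwm,
               threshold_fraction: float = 0.8) -> list[MotifHit]:
    """Windows scoring >= threshold_fraction * max attainable score.

    Overlapping calls on the same strand of the same sequence are resolved by
    keeping the higher score (ties: leftmost).
    """
    if not 0 < threshold_fraction <= 1:
        raise InputError("threshold_fraction must be in (0, 1]")
    cut = threshold_fraction * pwm.max_score
    cand = scores[scores["score"] >= cut]
    hits: list[MotifHit] = []
    for (_sid, _strand), grp in cand.groupby(["seq_id", "strand"], sort=False):
        # greedy: best score first (leftmost on ties), drop overlaps
        grp = grp.sort_values(["score", "start"], ascending=[False, True],
                              kind="stable")
        taken: list[tuple[int, int]] = []
        for row in grp.itertuples():
            if any(row.start < e and row.end > s for s, e in taken):
                continue
            taken.append((row.start, row.end))
            hits.append(MotifHit(row.seq_id, int(row.start), int(row.end),
                                 row.strand, float(row.score),
                                 float(row.score_fraction)))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def _best_overlapping(scores: pd.DataFrame, offset: int) -> float | None:
    over = scores[(scores["start"] <= offset) & (scores["end"] > offset)]
    if over.empty:
        return None
    return float(over["score"].max())


def snp_allele_delta(pwm: Pwm, seq: str, snp: tuple[int, str, str],
                     seq_id: str = "seq", snp_id: str = "snp",
                     threshold_fraction: float = 0.8) -> SnpDelta:
    """Predicted binding change of a SNP: best window overlapping the variant
    for each allele; delta = alt best - ref best.

    ``inside_site`` is True when an above-threshold site call of either allele
    overlaps the SNP; otherwise the delta is still reported over the raw best
    overlapping windows.
    """
    offset, ref, alt = snp
    seq = seq.upper()
    ref, alt = ref.upper(), alt.upper()
    if not 0 <= offset < len(seq):
        raise InputError("SNP offset outside sequence")
    if seq[offset] != ref:
        raise InputError(f"reference allele mismatch at offset {offset}: "
                         f"sequence has {seq[offset]}, SNP says {ref}")
    alt_seq = seq[:offset] + alt + seq[offset + 1:]
    sc_ref = scan(pwm, seq, seq_id)
    sc_alt = sc_ref if alt == ref else scan(pwm, alt_seq, seq_id)
    ref_best = _best_overlapping(sc_ref, offset)
    alt_best = _best_overlapping(sc_alt, offset)
    if ref_best is None or alt_best is None:
        # SNP too close to an edge for any full window: no overlap, no effect
        return SnpDelta(snp_id, seq_id, offset, ref, alt,
                        float("nan"), float("nan"), 0.0, False)
    inside = any(
        h.start <= offset < h.end
        for sc in (sc_ref, sc_alt)
        for h in call_sites(sc, pwm, threshold_fraction)
    )
    return SnpDelta(snp_id, seq_id, offset, ref, alt, ref_best, alt_best,
                    alt_best - ref_best, inside)


def prioritize_snps(deltas: list[SnpDelta]) -> pd.DataFrame:
    """Rank candidate regulatory SNPs: inside-site first, then |delta|
    descending; stable for ties."""
    if not deltas:
        raise InputError("no SNP deltas to prioritize")
    df = pd.DataFrame([vars(d) for d in deltas])
    df["abs_delta"] = df["delta"].abs()
    df = df.sort_values(["inside_site", "abs_delta"], ascending=[False, False],
                        kind="stable").drop(columns="abs_delta")
    return df.reset_index(drop=True)


def hits_to_bed(hits: list[MotifHit]) -> str:
    """BED6 lines; the score column scales score_fraction to 0-1000."""
    lines = []
    for i, h in enumerate(hits):
        bed_score = int(round(max(0.0, min(1.0, h.score_fraction)) * 1000))
        lines.append(f"{h.seq_id}\t{h.start}\t{h.end}\tsite{i + 1}\t{bed_score}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
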