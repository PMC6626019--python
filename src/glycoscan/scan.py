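"""Scoring profiles against protein sequences.

Implements local (unihit) Viterbi and forward scoring of a
:class:`~glycoscan.profiles.ProfileHMM` against an amino-acid sequence,
Gumbel calibration of bit scores for E-value computation, and iterative
extraction of multiple non-overlapping domain hits by masking.

Scores are reported in bits (log2-odds against the null model).  The
local model enters any match state uniformly (probability 1/M) and exits
freely after any match state; multiple domains per protein come from
re-running the aligner after masking previous hits with a score-neutral
symbol, not from a multihit loop state.

Coordinates are 0-based half-open internally and 1-based inclusive on
every :class:`DomainHit` and in every file written.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dp import NEG, forward_kernel, viterbi_kernel
from .errors import CalibrationError, InputError, NotCalibratedError
from .profiles import AA_INDEX, ProfileHMM

_LN2 = math.log(2.0)
_EULER = 0.5772156649015329

#: Index of the score-neutral symbol (log-odds 0 in every state).
NEUTRAL = 20

#: Ambiguity codes silently mapped to the score-neutral symbol.
AMBIGUOUS = frozenset("XBZUO")


@dataclass(frozen=True)
class DomainHit:
    """One scored placement of one family's profile on one protein.

    ``ali_start``/``ali_end`` are 1-based inclusive residue coordinates in
    the numbering of the input FASTA record.
    """

    protein_id: str
    accession: str
    family: str
    ali_start: int
    ali_end: int
    bit_score: float
    evalue: float
    stage: str = "direct"

    def __post_init__(self):
        if not (1 <= self.ali_start <= self.ali_end):
            raise InputError(
                f"{self.protein_id}/{self.accession}: bad coordinates "
                f"{self.ali_start}-{self.ali_end}"
            )
        if self.evalue < 0:
            raise InputError(f"{self.protein_id}: negative E-value")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


def encode_sequence(seq: str, protein_id: str = "?") -> np.ndarray:
    """Map a protein sequence to integer indices for the DP kernels.

    Ambiguity codes (X, B, Z, U, O) become the score-neutral symbol; a stop
    character ``*`` truncates the sequence with a warning; any other
    non-amino-acid symbol raises :class:`InputError` naming its position.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, sym in enumerate(seq.upper()):
        if sym in AA_INDEX:
            out[i] = AA_INDEX[sym]
        elif sym in AMBIGUOUS:
            out[i] = NEUTRAL
        elif sym == "*":
            warnings.warn(
                f"{protein_id}: stop symbol '*' at position {i + 1}; "
                f"sequence truncated"
            )
            return out[:i]
        else:
            raise InputError(
                f"{protein_id}: invalid symbol {sym!r} at position {i + 1}"
            )
    return out


def _score_matrices(model: ProfileHMM):
    """Log-odds emission scores (with neutral column) and log transitions."""
    bg = model.background
    msc = np.zeros((model.length, 21))
    isc = np.zeros((model.length, 21))
    with np.errstate(divide="ignore"):
        msc[:, :20] = np.log(model.match_emissions) - np.log(bg)[None, :]
        isc[:, :20] = np.log(model.insert_emissions) - np.log(bg)[None, :]
        ltr = np.where(model.transitions > 0.0, np.log(model.transitions), NEG)
    msc[~np.isfinite(msc)] = NEG
    isc[~np.isfinite(isc)] = NEG
    msc[:, 20] = 0.0
    isc[:, 20] = 0.0
    return msc, isc, ltr


def viterbi_local(model: ProfileHMM, seq: str | np.ndarray):
    """Best single local alignment of ``model`` against ``seq``.

    Returns ``(bit_score, ali_start, ali_end, (node_start, node_end))``
    with 1-based inclusive coordinates; ``(-inf, 0, 0, (0, 0))`` if no
    residue can be aligned.
    """
    x = encode_sequence(seq) if isinstance(seq, str) else seq
    if x.size == 0:
        raise InputError("empty sequence")
    msc, isc, ltr = _score_matrices(model)
    entry = -math.log(model.length)
    score, i0, i1, k0, k1 = viterbi_kernel(msc, isc, ltr, x, entry)
    if score <= NEG / 2:
        return float("-inf"), 0, 0, (0, 0)
    return score / _LN2, i0, i1, (k0, k1)


def forward_local(model: ProfileHMM, seq: str | np.ndarray) -> float:
    """Forward bit score: log2 sum over all local alignments.

    Always >= the Viterbi bit score for the same model and sequence.
    """
    x = encode_sequence(seq) if isinstance(seq, str) else seq
    if x.size == 0:
        raise InputError("empty sequence")
    msc, isc, ltr = _score_matrices(model)
    entry = -math.log(model.length)
    score = forward_kernel(msc, isc, ltr, x, entry)
    if score <= NEG / 2:
        return float("-inf")
    return score / _LN2


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel fit: lambda = pi/(sd*sqrt 6), mu = mean - gamma/lambda."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd == 0.0:
        raise CalibrationError("degenerate score distribution (sd = 0)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = scores.mean() - _EULER / lam
    return lam, mu


def calibrate_gumbel(
    model: ProfileHMM,
    n_samples: int = 500,
    seed: int = 0,
    length: int | None = None,
) -> tuple[float, float]:
    """Fit a Gumbel law to Viterbi bit scores of random sequences.

    ``n_samples`` i.i.d. sequences (length = model length unless given)
    are drawn from the model background and scored; lambda and mu are
    estimated by the method of moments::

        lambda = pi / (sd * sqrt(6));   mu = mean - gamma / lambda

    and stored on the model.  Deterministic for a fixed seed.
    """
    if n_samples < 200:
        raise CalibrationError("n_samples must be >= 200")
    rng = np.random.default_rng(seed)
    slen = length if length is not None else model.length
    msc, isc, ltr = _score_matrices(model)
    entry = -math.log(model.length)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        x = rng.choice(20, size=slen, p=model.background).astype(np.int64)
        s, *_ = viterbi_kernel(msc, isc, ltr, x, entry)
        scores[i] = s / _LN2
    try:
        lam, mu = fit_gumbel_moments(scores)
    except CalibrationError as exc:
        raise CalibrationError(f"{model.accession}: {exc}") from exc
    model.gumbel_lambda = lam
    model.gumbel_mu = mu
    model.calibration_length = slen
    return lam, mu


def score_to_evalue(
    model: ProfileHMM,
    bit_score: float,
    db_size: int,
    seq_length: int | None = None,
) -> float:
    """Expected number of equal-or-better scores in ``db_size`` sequences.

    E = db_size * (1 - exp(-exp(-lambda * (s - mu)))): strictly decreasing
    in the score and never exceeding ``db_size``.

    When ``seq_length`` is given, the Gumbel location is shifted by
    ``ln(seq_length / calibration_length) / lambda`` — the standard
    extreme-value correction for the number of available alignment start
    positions, which keeps E-values comparable across sequence lengths.
    """
    if not model.is_calibrated:
        raise NotCalibratedError(
            f"{model.accession}: model has no Gumbel parameters; "
            f"run calibrate_gumbel first"
        )
    if db_size < 1:
        raise InputError("db_size must be >= 1")
    if bit_score == float("-inf"):
        return float(db_size)
    mu = model.gumbel_mu
    if seq_length is not None and seq_length > 0:
        ref = model.calibration_length or model.length
        mu = mu + math.log(seq_length / ref) / model.gumbel_lambda
    z = model.gumbel_lambda * (bit_score - mu)
    # P(S >= s) under Gumbel; -expm1 keeps precision for tiny tails.
    p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    return db_size * p


def extract_domains(
    model: ProfileHMM,
    seq: str | np.ndarray,
    threshold_evalue: float,
    db_size: int,
    max_domains: int = 10,
    protein_id: str = "?",
    stage: str = "direct",
) -> list[DomainHit]:
    """All non-overlapping placements of one profile on one protein.

    Greedy iterative masking: the best local alignment is taken; if its
    E-value passes the threshold the hit is recorded and its aligned span
    masked with the score-neutral symbol, then the search repeats.  Stops
    when the threshold fails or ``max_domains`` is reached.  Hits are
    returned sorted by start coordinate and are pairwise non-overlapping.
    """
    if max_domains < 1:
        raise InputError("max_domains must be >= 1")
    if not model.is_calibrated:
        raise NotCalibratedError(f"{model.accession}: calibrate before scanning")
    x = encode_sequence(seq, protein_id) if isinstance(seq, str) else seq.copy()
    if x.size == 0:
        return []
    msc, isc, ltr = _score_matrices(model)
    entry = -math.log(model.length)
    masked = np.zeros(x.size, dtype=bool)
    hits: list[DomainHit] = []
    while len(hits) < max_domains:
        score, i0, i1, _k0, _k1 = viterbi_kernel(msc, isc, ltr, x, entry)
        if score <= NEG / 2:
            break
        bits = score / _LN2
        evalue = score_to_evalue(model, bits, db_size, seq_length=x.size)
        if evalue > threshold_evalue:
            break
        # Alignment span, 0-based half-open; clip to unmasked residues so
        # hits can never overlap a previously extracted domain.
        lo, hi = i0 - 1, i1
        runs = _unmasked_runs(masked, lo, hi)
        if runs:
            start, end = max(runs, key=lambda r: r[1] - r[0])
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    accession=model.accession,
                    family=model.name,
                    ali_start=start + 1,
                    ali_end=end,
                    bit_score=bits,
                    evalue=evalue,
                    stage=stage,
                )
            )
        x[lo:hi] = NEUTRAL
        masked[lo:hi] = True
    hits.sort(key=lambda h: h.ali_start)
    return hits


def _unmasked_runs(masked: np.ndarray, lo: int, hi: int):
    """Contiguous unmasked sub-intervals of [lo, hi), as (start, end)."""
    runs = []
    start = None
    for i in range(lo, hi):
        if not masked[i]:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, hi))
    return runs


# ---------------------------------------------------------------------------
# Hit table I/O (stable subset of domtblout semantics, as TSV)
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "protein_id",
    "accession",
    "family",
    "ali_start",
    "ali_end",
    "bit_score",
    "evalue",
    "stage",
]


def hits_to_frame(hits: list[DomainHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(h, c) for c in HIT_COLUMNS] for h in hits], columns=HIT_COLUMNS
    )


def write_hit_table(hits: list[DomainHit], path) -> None:
    """Write hits as a tab-separated table with 1-based inclusive coords."""
    df = hits_to_frame(hits)
    df["bit_score"] = df["bit_score"].map(lambda v: f"{v:.4f}")
    df["evalue"] = df["evalue"].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "family": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"hit table {path} missing columns: {sorted(missing)}")
    return [
        DomainHit(
            protein_id=str(r.protein_id),
            accession=str(r.accession),
            family=str(r.family),
            ali_start=int(r.ali_start),
            ali_end=int(r.ali_end),
            bit_score=float(r.bit_score),
            evalue=float(r.evalue),
            stage=str(r.stage),
        )
        for r in df.itertuples()
    ]
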