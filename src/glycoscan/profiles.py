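"""Profile hidden Markov models of protein domain families.

A :class:`ProfileHMM` is the classical plan-7-style model restricted to the
three core state types (match / insert / delete) with per-node emission and
transition probabilities.  Models can be estimated from a seed multiple
alignment (:func:`build_profile`) or exchanged on disk in a HMMER3-ASCII
compatible dialect (:func:`read_profile_db` / :func:`write_profile_db`), so
an annotation run needs no external profile downloads.

Probabilities are stored in probability space in memory and as negative
natural logarithms on disk, with ``*`` encoding probability zero, following
the HMMER3 text convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NoMatchColumnsError, ParseError

#: Canonical amino-acid alphabet, in the column order used on disk.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Column order of the per-node transition matrix.
TRANSITIONS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
_T = {name: i for i, name in enumerate(TRANSITIONS)}

_NORM_TOL = 1e-9


def uniform_background() -> np.ndarray:
    """Uniform null model over the 20 amino acids."""
    return np.full(20, 1.0 / 20.0)


@dataclass
class ProfileHMM:
    """Position-specific emission/transition model for one domain family.

    Attributes
    ----------
    accession, name:
        Stable identifier (e.g. ``PF00150``) and human-readable family name.
    match_emissions, insert_emissions:
        ``(M, 20)`` arrays of emission probabilities, one row per node.
    transitions:
        ``(M, 7)`` array in the column order :data:`TRANSITIONS`; each of
        the three outgoing groups (from M, from I, from D) sums to one.
    background:
        20-vector of null-model residue frequencies.
    gumbel_lambda, gumbel_mu:
        Extreme-value parameters for bit-score -> E-value conversion;
        ``None`` until calibrated.
    """

    accession: str
    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=uniform_background)
    gumbel_lambda: float | None = None
    gumbel_mu: float | None = None
    #: Length of the random sequences used at calibration time; E-value
    #: computation rescales the Gumbel location for other search lengths.
    calibration_length: int | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        """Number of match states M."""
        return self.match_emissions.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.gumbel_lambda is not None and self.gumbel_mu is not None

    def validate(self) -> None:
        """Raise :class:`InputError` if any model invariant is violated."""
        m = self.length
        if m < 1:
            raise InputError(f"{self.accession}: model must have M >= 1")
        for label, arr, ncol in (
            ("match_emissions", self.match_emissions, 20),
            ("insert_emissions", self.insert_emissions, 20),
            ("transitions", self.transitions, 7),
        ):
            if arr.shape != (m, ncol):
                raise InputError(
                    f"{self.accession}: {label} has shape {arr.shape}, "
                    f"expected {(m, ncol)}"
                )
        for label, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            bad = np.nonzero(np.abs(arr.sum(axis=1) - 1.0) > _NORM_TOL)[0]
            if bad.size:
                raise InputError(
                    f"{self.accession}: {label} row for node {bad[0] + 1} "
                    f"does not sum to 1"
                )
        groups = {"M": (0, 1, 2), "I": (3, 4), "D": (5, 6)}
        for src, cols in groups.items():
            sums = self.transitions[:, list(cols)].sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > _NORM_TOL)[0]
            if bad.size:
                raise InputError(
                    f"{self.accession}: transitions from {src} at node "
                    f"{bad[0] + 1} do not sum to 1"
                )
        if abs(self.background.sum() - 1.0) > _NORM_TOL:
            raise InputError(f"{self.accession}: background does not sum to 1")

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        idx = np.argmax(self.match_emissions, axis=1)
        return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class SeedAlignment:
    """A gapped multiple alignment used to estimate a profile.

    Rows are equal-length strings over the 20 amino acids plus ``-``.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("seed alignment has no rows")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise InputError(
                    f"row {rid!r} has length {len(row)}, expected {width}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path) -> "SeedAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids=ids, rows=rows)


def build_profile(
    aln: SeedAlignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    match_occupancy: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose residue occupancy is at least ``match_occupancy``
    (default 50 %, ties counting as match) become match states.  Emissions
    are smoothed with background-proportional pseudocounts::

        e(k, a) = (count(k, a) + w * bg(a)) / (n_k + w)

    where ``n_k`` is the number of residues observed in the column and ``w``
    the pseudocount weight.  Transition probabilities are estimated from the
    per-row state paths with the analogous smoothing toward a uniform prior
    over each outgoing group.

    Raises
    ------
    NoMatchColumnsError
        If no column reaches the occupancy threshold.
    ParseError
        If a row contains a symbol outside the amino-acid alphabet + ``-``.
    """
    if pseudocount_weight <= 0:
        raise InputError("pseudocount_weight must be > 0")
    bg = uniform_background() if background is None else np.asarray(background, float)

    n_rows, n_cols = aln.n_rows, aln.n_cols
    enc = np.empty((n_rows, n_cols), dtype=np.int8)
    for r, row in enumerate(aln.rows):
        for c, sym in enumerate(row):
            if sym == "-":
                enc[r, c] = -1
            elif sym in AA_INDEX:
                enc[r, c] = AA_INDEX[sym]
            else:
                rid = aln.ids[r] if r < len(aln.ids) else str(r)
                raise ParseError(
                    f"invalid symbol {sym!r} in row {rid!r} "
                    f"(row {r + 1}, column {c + 1})"
                )

    occupancy = (enc >= 0).sum(axis=0) / n_rows
    match_cols = np.nonzero(occupancy >= match_occupancy)[0]
    if match_cols.size == 0:
        raise NoMatchColumnsError("alignment has no match columns")
    m = match_cols.size

    w = pseudocount_weight
    match_e = np.empty((m, 20))
    for k, c in enumerate(match_cols):
        col = enc[:, c]
        residues = col[col >= 0]
        counts = np.bincount(residues, minlength=20).astype(float)
        match_e[k] = (counts + w * bg) / (residues.size + w)

    # Insert columns between match columns c_k and c_{k+1} belong to node
    # k+1 (1-based); residues outside the first..last match column span are
    # not modelled and are ignored.
    insert_e = np.empty((m, 20))
    col_node = np.full(n_cols, -1, dtype=int)  # insert column -> node (0-based)
    for k in range(m):
        lo = match_cols[k] + 1
        hi = match_cols[k + 1] if k + 1 < m else match_cols[-1]  # none after last
        col_node[lo:hi] = k
    for k in range(m):
        cols = np.nonzero(col_node == k)[0]
        if cols.size:
            residues = enc[:, cols].ravel()
            residues = residues[residues >= 0]
        else:
            residues = np.empty(0, dtype=np.int8)
        counts = np.bincount(residues, minlength=20).astype(float)
        insert_e[k] = (counts + w * bg) / (residues.size + w)

    # Per-row state paths over the match-column span; begin/end moves are
    # not attributed to any node.
    t_counts = np.zeros((m, 7))
    is_match = np.zeros(n_cols, dtype=bool)
    is_match[match_cols] = True
    node_of_match = np.full(n_cols, -1, dtype=int)
    node_of_match[match_cols] = np.arange(m)
    first, last = match_cols[0], match_cols[-1]
    for r in range(n_rows):
        prev: tuple[str, int] | None = None  # (state, node 0-based)
        for c in range(first, last + 1):
            if is_match[c]:
                state = ("M" if enc[r, c] >= 0 else "D", node_of_match[c])
            elif enc[r, c] >= 0:
                state = ("I", col_node[c])
            else:
                continue
            if prev is not None:
                move = prev[0] + state[0]
                if move in _T:
                    t_counts[prev[1], _T[move]] += 1
            prev = state

    trans = np.empty((m, 7))
    for cols in ((0, 1, 2), (3, 4), (5, 6)):
        grp = t_counts[:, list(cols)]
        totals = grp.sum(axis=1, keepdims=True)
        prior = 1.0 / len(cols)
        trans[:, list(cols)] = (grp + w * prior) / (totals + w)

    model = ProfileHMM(
        accession="",
        name="",
        match_emissions=match_e,
        insert_emissions=insert_e,
        transitions=trans,
        background=bg,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# HMMER3-ASCII dialect
# ---------------------------------------------------------------------------

def _num(p: float) -> str:
    """Encode a probability as negative natural log ('*' for zero)."""
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.7f}"


def _prob(token: str, where: str) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError as exc:
        raise ParseError(f"bad numeric field {token!r} in {where}") from exc


def write_profile_db(models: list[ProfileHMM], path) -> None:
    """Write models to ``path`` in the HMMER3-ASCII dialect.

    Each record carries NAME/ACC/LENG/ALPH headers, an optional STATS line
    when the model is calibrated, a COMPO line holding the null model, and
    one three-line block per node, terminated by ``//``.  Every model is
    validated first; an unnormalized model is refused.
    """
    for model in models:
        model.validate()
    with open(path, "w") as fh:
        for model in models:
            fh.write("HMMER3/f [glycoscan profile dialect]\n")
            fh.write(f"NAME  {model.name}\n")
            fh.write(f"ACC   {model.accession}\n")
            fh.write(f"LENG  {model.length}\n")
            fh.write("ALPH  amino\n")
            if model.is_calibrated:
                fh.write(
                    f"STATS LOCAL VITERBI {model.gumbel_mu:.5f} "
                    f"{model.gumbel_lambda:.5f}\n"
                )
            fh.write("HMM" + "".join(f"{a:>10}" for a in AMINO_ACIDS) + "\n")
            fh.write(
                "    "
                + "".join(f"{t.lower()[0]}->{t.lower()[1]:<7}" for t in TRANSITIONS)
                + "\n"
            )
            fh.write(
                "  COMPO "
                + " ".join(f"{_num(p):>9}" for p in model.background)
                + "\n"
            )
            for k in range(model.length):
                fh.write(
                    f"{k + 1:>7} "
                    + " ".join(f"{_num(p):>9}" for p in model.match_emissions[k])
                    + "\n"
                )
                fh.write(
                    "        "
                    + " ".join(f"{_num(p):>9}" for p in model.insert_emissions[k])
                    + "\n"
                )
                fh.write(
                    "        "
                    + " ".join(f"{_num(p):>9}" for p in model.transitions[k])
                    + "\n"
                )
            fh.write("//\n")


def read_profile_db(path) -> list[ProfileHMM]:
    """Read all profile records from a file in the dialect above.

    Probabilities are recovered from the stored negative-log values (round
    trips are lossless to well under 1e-6).  An empty file yields an empty
    list; a truncated record or a node-count/LENG mismatch raises
    :class:`ParseError` naming the record.
    """
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith("HMMER3"):
            raise ParseError(f"expected HMMER3 header at line {i + 1}, got {line!r}")
        name = acc = ""
        leng = -1
        mu = lam = None
        background = None
        i += 1
        while i < n and not lines[i].startswith("HMM"):
            key, _, val = lines[i].partition(" ")
            val = val.strip()
            if key == "NAME":
                name = val
            elif key == "ACC":
                acc = val
            elif key == "LENG":
                leng = int(val)
            elif key == "STATS":
                parts = val.split()
                if len(parts) != 4 or parts[0] != "LOCAL" or parts[1] != "VITERBI":
                    raise ParseError(f"record {name!r}: bad STATS line {val!r}")
                mu, lam = float(parts[2]), float(parts[3])
            i += 1
        if i >= n:
            raise ParseError(f"record {name!r}: truncated header (no HMM line)")
        if leng < 1:
            raise ParseError(f"record {name!r}: missing or invalid LENG")
        i += 2  # HMM column header + transition header
        if i < n and lines[i].strip().startswith("COMPO"):
            toks = lines[i].split()[1:]
            if len(toks) != 20:
                raise ParseError(f"record {name!r}: COMPO line has {len(toks)} fields")
            background = np.array(
                [_prob(t, f"COMPO of {name!r}") for t in toks]
            )
            i += 1
        match_e, insert_e, trans = [], [], []
        while i < n and lines[i].strip() != "//":
            header = lines[i].split()
            if len(header) != 21:
                raise ParseError(
                    f"record {name!r}: malformed match line at line {i + 1}"
                )
            node = int(header[0])
            if node != len(match_e) + 1:
                raise ParseError(
                    f"record {name!r}: node {node} out of order at line {i + 1}"
                )
            if i + 2 >= n:
                raise ParseError(f"record {name!r}: truncated node block")
            match_e.append([_prob(t, f"node {node} of {name!r}") for t in header[1:]])
            ins = lines[i + 1].split()
            tr = lines[i + 2].split()
            if len(ins) != 20 or len(tr) != 7:
                raise ParseError(f"record {name!r}: malformed node {node} block")
            insert_e.append([_prob(t, f"node {node} of {name!r}") for t in ins])
            trans.append([_prob(t, f"node {node} of {name!r}") for t in tr])
            i += 3
        if i >= n:
            raise ParseError(f"record {name!r}: missing '//' terminator")
        i += 1  # consume '//'
        if len(match_e) != leng:
            raise ParseError(
                f"record {name!r}: LENG {leng} but {len(match_e)} nodes found"
            )
        # Restore exact normalization lost to fixed-precision text encoding;
        # the perturbation is far below the 1e-6 round-trip tolerance.
        me = _renorm(np.array(match_e))
        ie = _renorm(np.array(insert_e))
        tr = np.array(trans)
        for cols in ((0, 1, 2), (3, 4), (5, 6)):
            tr[:, list(cols)] = _renorm(tr[:, list(cols)])
        bg = background if background is not None else uniform_background()
        bg = bg / bg.sum()
        model = ProfileHMM(
            accession=acc,
            name=name,
            match_emissions=me,
            insert_emissions=ie,
            transitions=tr,
            background=bg,
            gumbel_lambda=lam,
            gumbel_mu=mu,
        )
        models.append(model)
    return models


def _renorm(arr: np.ndarray) -> np.ndarray:
    sums = arr.sum(axis=1, keepdims=True)
    sums[sums == 0.0] = 1.0
    return arr / sums
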