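"""The two-stage sequential annotation strategy.

Stage 1 searches only the small set of target profiles ("domains of
interest") against every protein with a permissive E-value threshold: fast
and deliberately inaccurate.  Stage 2 re-scans only the stage-1 candidate
proteins against the *entire* profile database at a strict per-domain
threshold, which reveals every associated domain (accessory modules,
esterases, ...) and discards stage-1 false positives — any candidate left
without a target-family domain at the strict threshold.

Because the stage-1 threshold is at least as permissive as the stage-2
threshold and stage 2 recomputes every hit from scratch, the sequential
result is *identical* to a direct scan of all proteins against the full
database (restricted to proteins retaining a target-family domain), while
scoring far fewer (protein x profile) pairs.  :func:`run_direct` implements
that comparator and doubles as the correctness oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigError, InputError
from .profiles import ProfileHMM
from .scan import DomainHit, extract_domains, score_to_evalue, viterbi_local

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a sequential annotation run.

    ``stage1_evalue`` must be >= ``stage2_evalue``: this is what makes the
    sequential result provably equal to the direct scan.  The E-value
    database size is shared by both stages (either the number of input
    sequences, or a fixed value) for the same reason.
    """

    target_accessions: frozenset[str] = field(default_factory=frozenset)
    stage1_evalue: float = 10.0
    stage2_evalue: float = 1e-5
    db_size_policy: str = "n_sequences"  # or "fixed"
    db_size_fixed: int | None = None
    max_domains_per_protein: int = 10
    seed: int = 0

    def __post_init__(self):
        self.target_accessions = frozenset(self.target_accessions)
        try:
            # YAML 1.1 reads unquoted "1e-9" as a string; be forgiving.
            self.stage1_evalue = float(self.stage1_evalue)
            self.stage2_evalue = float(self.stage2_evalue)
            self.max_domains_per_protein = int(self.max_domains_per_protein)
            self.seed = int(self.seed)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric pipeline parameter: {exc}") from exc
        if self.stage1_evalue <= 0 or self.stage2_evalue <= 0:
            raise ConfigError("E-value thresholds must be > 0")
        if self.stage1_evalue < self.stage2_evalue:
            raise ConfigError(
                "stage1_evalue must be >= stage2_evalue "
                "(stage 1 is the permissive pass)"
            )
        if self.db_size_policy not in ("n_sequences", "fixed"):
            raise ConfigError(f"unknown db_size_policy {self.db_size_policy!r}")
        if self.db_size_policy == "fixed" and not self.db_size_fixed:
            raise ConfigError("db_size_policy 'fixed' requires db_size_fixed")
        if self.max_domains_per_protein < 1:
            raise ConfigError("max_domains_per_protein must be >= 1")

    def db_size(self, n_sequences: int) -> int:
        if self.db_size_policy == "fixed":
            return int(self.db_size_fixed)
        return max(n_sequences, 1)


@dataclass
class RunStats:
    """Scoring-work accounting: one call = one (protein x profile) pair."""

    n_proteins: int = 0
    n_candidates: int = 0
    stage1_calls: int = 0
    stage2_calls: int = 0

    @property
    def total_calls(self) -> int:
        return self.stage1_calls + self.stage2_calls


def _check_targets(
    targets: list[ProfileHMM], cfg: PipelineConfig, db_size: int, n_proteins: int
):
    if not targets:
        raise InputError("nothing to hunt: empty target profile set")
    if n_proteins and cfg.stage1_evalue > db_size:
        raise ConfigError(
            f"stage1_evalue {cfg.stage1_evalue} exceeds db_size {db_size}; "
            f"the largest meaningful threshold is the database size"
        )


def stage1_search(
    proteins: dict[str, str],
    targets: list[ProfileHMM],
    cfg: PipelineConfig,
    stats: RunStats | None = None,
) -> tuple[set[str], list[DomainHit]]:
    """Fast targeted first pass.

    A protein is a candidate iff at least one target profile places its
    best local alignment at E <= ``stage1_evalue``.  Only the single best
    placement per (protein, target) is examined — coordinates are
    recorded for logging but discarded by the pipeline.
    """
    db_size = cfg.db_size(len(proteins))
    _check_targets(targets, cfg, db_size, len(proteins))
    stats = stats if stats is not None else RunStats()
    candidates: set[str] = set()
    hits: list[DomainHit] = []
    for pid, seq in proteins.items():
        for model in targets:
            stats.stage1_calls += 1
            bits, i0, i1, _nodes = viterbi_local(model, seq)
            if bits == float("-inf"):
                continue
            evalue = score_to_evalue(model, bits, db_size, seq_length=len(seq))
            if evalue <= cfg.stage1_evalue:
                candidates.add(pid)
                hits.append(
                    DomainHit(
                        protein_id=pid,
                        accession=model.accession,
                        family=model.name,
                        ali_start=i0,
                        ali_end=i1,
                        bit_score=bits,
                        evalue=evalue,
                        stage="stage1",
                    )
                )
    stats.n_proteins = len(proteins)
    stats.n_candidates = len(candidates)
    logger.info("stage1: %d/%d candidates", len(candidates), len(proteins))
    return candidates, hits


def stage2_scan(
    candidates: set[str],
    proteins: dict[str, str],
    full_db: list[ProfileHMM],
    cfg: PipelineConfig,
    stats: RunStats | None = None,
) -> dict[str, list[DomainHit]]:
    """Full-database rescan of the candidates at the strict threshold.

    Every candidate is scanned against every profile with iterative
    domain extraction; candidates with no target-family domain at
    ``stage2_evalue`` are dropped (false-positive removal).
    """
    missing = candidates - set(proteins)
    if missing:
        raise InputError(f"candidate ids absent from proteome: {sorted(missing)}")
    db_size = cfg.db_size(len(proteins))
    stats = stats if stats is not None else RunStats()
    out: dict[str, list[DomainHit]] = {}
    for pid in sorted(candidates):
        seq = proteins[pid]
        hits: list[DomainHit] = []
        for model in full_db:
            stats.stage2_calls += 1
            hits.extend(
                extract_domains(
                    model,
                    seq,
                    threshold_evalue=cfg.stage2_evalue,
                    db_size=db_size,
                    max_domains=cfg.max_domains_per_protein,
                    protein_id=pid,
                    stage="stage2",
                )
            )
        if any(h.accession in cfg.target_accessions for h in hits):
            hits.sort(key=lambda h: (h.ali_start, h.accession))
            out[pid] = hits
    logger.info("stage2: %d/%d candidates retained", len(out), len(candidates))
    return out


def run_sequential(
    proteins: dict[str, str],
    full_db: list[ProfileHMM],
    cfg: PipelineConfig,
    stats: RunStats | None = None,
) -> dict[str, list[DomainHit]]:
    """Stage-1 targeted search followed by stage-2 full rescan."""
    stats = stats if stats is not None else RunStats()
    targets = [m for m in full_db if m.accession in cfg.target_accessions]
    candidates, _stage1_hits = stage1_search(proteins, targets, cfg, stats)
    return stage2_scan(candidates, proteins, full_db, cfg, stats)


def run_direct(
    proteins: dict[str, str],
    full_db: list[ProfileHMM],
    cfg: PipelineConfig,
    stats: RunStats | None = None,
) -> dict[str, list[DomainHit]]:
    """Direct scan comparator: every protein against every profile.

    Keeps proteins with at least one target-family domain at the strict
    threshold.  Hits are tagged ``stage2`` so the sequential result can be
    compared field-for-field.
    """
    if not cfg.target_accessions:
        raise InputError("nothing to hunt: empty target accession set")
    db_size = cfg.db_size(len(proteins))
    stats = stats if stats is not None else RunStats()
    stats.n_proteins = len(proteins)
    out: dict[str, list[DomainHit]] = {}
    for pid in sorted(proteins):
        seq = proteins[pid]
        hits: list[DomainHit] = []
        for model in full_db:
            stats.stage2_calls += 1
            hits.extend(
                extract_domains(
                    model,
                    seq,
                    threshold_evalue=cfg.stage2_evalue,
                    db_size=db_size,
                    max_domains=cfg.max_domains_per_protein,
                    protein_id=pid,
                    stage="stage2",
                )
            )
        if any(h.accession in cfg.target_accessions for h in hits):
            hits.sort(key=lambda h: (h.ali_start, h.accession))
            out[pid] = hits
    return out
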