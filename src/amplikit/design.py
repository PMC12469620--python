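"""Primer design: amplicon geometries and the iterative design waterfall.

Three geometries serve a 150 bp paired-end targeted amplicon sequencing
(TAS) readout:

* **TAS-opt** — both primer 3' ends sit 60–100 bp from the target base,
  roughly equidistant, with an optimum product of 190 bp, so the target is
  covered by both the forward and the reverse 150 bp read.
* **Relaxed-right** — the forward primer keeps the 60–100 bp anchor; the
  reverse side is free, product capped at 500 bp. Only one read covers the
  target.
* **Relaxed-left** — the mirror image: reverse primer anchored, forward
  side free.

Design runs as a waterfall: TAS-opt is attempted for every site; sites with
no viable TAS-opt pair get a Relaxed-right attempt; remaining failures get
Relaxed-left; a site failing all three is reported as undesignable.
Fallback triggers only on design failure — a pair later rejected for
concerning off-targets is reported, not re-designed.

The built-in engine enumerates candidate primers inside the template
window, filters on sequence quality (length, GC, melting temperature,
homopolymer runs, no N), and ranks candidate pairs by a penalty combining
Tm deviation, Tm balance, product-size deviation from the optimum and — for
TAS-opt — asymmetry of the two target distances. Melting temperatures use
nearest-neighbour thermodynamics (50 nM primer, 50 mM Na+).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .targets import TargetSite, TemplateWindow, extract_window

logger = logging.getLogger(__name__)


class DesignModeName(str, enum.Enum):
    TAS_OPT = "TAS_OPT"
    RELAXED_RIGHT = "RELAXED_RIGHT"
    RELAXED_LEFT = "RELAXED_LEFT"


#: Human-readable labels used in primer names and report columns.
MODE_LABELS = {
    DesignModeName.TAS_OPT: "TAS-opt",
    DesignModeName.RELAXED_RIGHT: "Relaxed-right",
    DesignModeName.RELAXED_LEFT: "Relaxed-left",
}

WATERFALL_ORDER = (
    DesignModeName.TAS_OPT,
    DesignModeName.RELAXED_RIGHT,
    DesignModeName.RELAXED_LEFT,
)


@dataclass(frozen=True)
class DesignMode:
    """Geometry of one design mode.

    ``anchor_side`` names which primer keeps the TAS-opt distance
    constraint: ``"both"`` (TAS-opt), ``"left"`` (Relaxed-right: forward
    anchored, reverse free) or ``"right"`` (Relaxed-left).
    """

    name: DesignModeName
    optimal_product: int
    min_product: int
    max_product: int
    anchor_side: str
    target_distance_range: tuple[int, int] = (60, 100)

    def __post_init__(self) -> None:
        if self.anchor_side not in ("both", "left", "right"):
            raise ValueError(f"bad anchor_side {self.anchor_side!r}")
        if self.max_product < self.optimal_product:
            raise ValueError("max_product must be >= optimal_product")

    @property
    def label(self) -> str:
        return MODE_LABELS[self.name]


def default_modes(
    tas_product_range: tuple[int, int] = (150, 200),
    tas_optimal_product: int = 190,
    relaxed_max_product: int = 500,
    target_distance_range: tuple[int, int] = (60, 100),
) -> dict[DesignModeName, DesignMode]:
    """The three stock geometries with their default numeric constraints."""
    lo, hi = tas_product_range
    return {
        DesignModeName.TAS_OPT: DesignMode(
            DesignModeName.TAS_OPT, tas_optimal_product, lo, hi, "both",
            target_distance_range,
        ),
        DesignModeName.RELAXED_RIGHT: DesignMode(
            DesignModeName.RELAXED_RIGHT, tas_optimal_product, lo,
            relaxed_max_product, "left", target_distance_range,
        ),
        DesignModeName.RELAXED_LEFT: DesignMode(
            DesignModeName.RELAXED_LEFT, tas_optimal_product, lo,
            relaxed_max_product, "right", target_distance_range,
        ),
    }


@dataclass(frozen=True)
class EngineParams:
    """Quality constraints and ranking weights of the built-in engine.

    Only geometry is mode-specific; these apply to every mode. The Tm
    window (50–66 °C, optimum 58) reflects nearest-neighbour Tm of typical
    18–27-mers on near-50 % GC genomic sequence at 50 nM primer / 50 mM
    monovalent salt.
    """

    primer_len_range: tuple[int, int] = (18, 27)
    tm_range: tuple[float, float] = (50.0, 66.0)
    tm_optimum: float = 58.0
    gc_range: tuple[float, float] = (20.0, 80.0)
    max_homopolymer: int = 5
    max_candidates_per_side: int = 50
    w_tm: float = 1.0
    w_tm_diff: float = 1.0
    w_product: float = 0.05
    w_symmetry: float = 0.2


@dataclass(frozen=True)
class DesignSpec:
    """Concrete, window-resolved constraints for one design attempt.

    Distances are measured from the primer 3' end to the target base;
    ``None`` means that side is unconstrained (free up to the product cap).
    Offsets are 0-based within the window.
    """

    mode: DesignMode
    target_offset: int
    fwd_dist_range: Optional[tuple[int, int]]
    rev_dist_range: Optional[tuple[int, int]]
    product_range: tuple[int, int]
    optimal_product: int

    def to_engine_record(self, sequence_id: str, template: str) -> dict:
        """Machine-readable engine input record for audit output."""
        return {
            "SEQUENCE_ID": sequence_id,
            "SEQUENCE_TEMPLATE": template,
            "SEQUENCE_TARGET": f"{self.target_offset},1",
            "MODE": self.mode.name.value,
            "PRODUCT_SIZE_RANGE": f"{self.product_range[0]}-{self.product_range[1]}",
            "PRODUCT_OPT_SIZE": self.optimal_product,
            "FWD_TARGET_DISTANCE": self.fwd_dist_range,
            "REV_TARGET_DISTANCE": self.rev_dist_range,
        }


@dataclass(frozen=True)
class PrimerPair:
    """A designed forward/reverse primer pair with genomic placement.

    ``amplicon_start``/``amplicon_end`` are 0-based half-open on the
    contig; the target base lies strictly inside the interval.
    """

    pair_name: str
    fwd_name: str
    rev_name: str
    fwd_seq: str
    rev_seq: str
    fwd_tm: float
    rev_tm: float
    mode: DesignModeName
    predicted_product: int
    amplicon_start: int
    amplicon_end: int
    chrom: str

    def __post_init__(self) -> None:
        for s in (self.fwd_seq, self.rev_seq):
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"primer sequence invalid: {s!r}")
        if self.amplicon_end - self.amplicon_start != self.predicted_product:
            raise ValueError("amplicon interval inconsistent with product size")

    @property
    def mode_label(self) -> str:
        return MODE_LABELS[self.mode]


@dataclass
class DesignOutcome:
    """Per-site result of the waterfall: at most one retained pair."""

    site: TargetSite
    pair: Optional[PrimerPair]
    attempted_modes: list[DesignModeName] = field(default_factory=list)

    @property
    def primer3_ok(self) -> bool:
        return self.pair is not None


class DesignInfeasible(ValueError):
    """The window cannot host the requested geometry (treated as failure)."""


class EngineError(RuntimeError):
    """Malformed engine settings (distinct from 'no pair found')."""


# ---------------------------------------------------------------------------
# Candidate enumeration


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature (°C), 50 nM primer, 50 mM Na+."""
    return float(MeltingTemp.Tm_NN(seq, dnac1=50, dnac2=0, Na=50))


@dataclass(frozen=True)
class _Candidate:
    # window-local coordinates, half-open footprint on the plus strand
    start: int
    end: int
    seq: str  # 5'->3' primer sequence
    tm: float
    penalty: float


def _passes_quality(seq: str, params: EngineParams) -> bool:
    if set(seq) - set("ACGT"):
        return False
    lo, hi = params.gc_range
    if not (lo <= _gc_percent(seq) <= hi):
        return False
    if _max_run(seq) > params.max_homopolymer:
        return False
    return True


def _enumerate_side(
    window: TemplateWindow,
    three_prime_positions: Iterable[int],
    is_forward: bool,
    params: EngineParams,
) -> list[_Candidate]:
    """Candidates for one side, keyed by the window index of the 3' base.

    For the forward primer the 3' base is the rightmost footprint base; for
    the reverse primer (minus strand) it is the leftmost.
    """
    seq = window.seq
    n = len(seq)
    lmin, lmax = params.primer_len_range
    out: list[_Candidate] = []
    for p3 in three_prime_positions:
        if not (0 <= p3 < n):
            continue
        for length in range(lmin, lmax + 1):
            if is_forward:
                start, end = p3 - length + 1, p3 + 1
            else:
                start, end = p3, p3 + length
            if start < 0 or end > n:
                continue
            footprint = seq[start:end]
            primer = footprint if is_forward else str(
                Seq(footprint).reverse_complement()
            )
            if not _passes_quality(primer, params):
                continue
            tm = primer_tm(primer)
            if not (params.tm_range[0] <= tm <= params.tm_range[1]):
                continue
            out.append(
                _Candidate(start, end, primer, tm,
                           params.w_tm * abs(tm - params.tm_optimum))
            )
    out.sort(key=lambda c: c.penalty)
    return out[: params.max_candidates_per_side]


def build_design_spec(
    window: TemplateWindow, mode: DesignMode, params: EngineParams = EngineParams()
) -> DesignSpec:
    """Resolve a mode's geometry against a concrete template window.

    Raises :class:`DesignInfeasible` when the window cannot contain the
    mode's maximum product around the target.
    """
    t = window.target_offset
    n = len(window.seq)
    dmin, dmax = mode.target_distance_range
    lmin = params.primer_len_range[0]
    anchored = (dmin, dmax)
    if mode.anchor_side == "both":
        fwd, rev = anchored, anchored
    elif mode.anchor_side == "left":
        fwd, rev = anchored, None
    else:
        fwd, rev = None, anchored
    # each side must fit a minimal primer at its minimal target distance
    need_left = (dmin + lmin - 1) if fwd is not None else lmin
    need_right = (dmin + lmin - 1) if rev is not None else lmin
    if t < need_left or (n - 1 - t) < need_right:
        raise DesignInfeasible(
            f"window too short for {mode.label}: target at {t} in {n} bp window"
        )
    return DesignSpec(
        mode=mode,
        target_offset=t,
        fwd_dist_range=fwd,
        rev_dist_range=rev,
        product_range=(mode.min_product, mode.max_product),
        optimal_product=mode.optimal_product,
    )


def design_pair(
    window: TemplateWindow,
    spec: DesignSpec,
    params: EngineParams = EngineParams(),
) -> Optional[PrimerPair]:
    """Pick the best-ranked primer pair satisfying ``spec``, or ``None``.

    Returns ``None`` when no candidate pair satisfies the constraints (a
    design failure, not an error). Raises :class:`EngineError` for
    malformed settings.
    """
    if spec.product_range[0] > spec.product_range[1]:
        raise EngineError(f"empty product range {spec.product_range}")
    t = spec.target_offset
    n = len(window.seq)
    pmin, pmax = spec.product_range

    if spec.fwd_dist_range is not None:
        f_positions = [t - d for d in
                       range(spec.fwd_dist_range[0], spec.fwd_dist_range[1] + 1)]
    else:
        f_positions = [t - d for d in range(1, pmax)]
    if spec.rev_dist_range is not None:
        r_positions = [t + d for d in
                       range(spec.rev_dist_range[0], spec.rev_dist_range[1] + 1)]
    else:
        r_positions = [t + d for d in range(1, pmax)]

    fwd_cands = _enumerate_side(window, f_positions, True, params)
    rev_cands = _enumerate_side(window, r_positions, False, params)
    if not fwd_cands or not rev_cands:
        return None

    best: tuple[float, _Candidate, _Candidate] | None = None
    for f in fwd_cands:
        for r in rev_cands:
            if r.start <= f.end:
                continue  # primers must not touch or overlap
            product = r.end - f.start
            if not (pmin <= product <= pmax):
                continue
            pen = (
                f.penalty
                + r.penalty
                + params.w_tm_diff * abs(f.tm - r.tm)
                + params.w_product * abs(product - spec.optimal_product)
            )
            if spec.mode.anchor_side == "both":
                d_f = t - (f.end - 1)
                d_r = r.start - t
                pen += params.w_symmetry * abs(d_f - d_r)
            if best is None or pen < best[0]:
                best = (pen, f, r)
    if best is None:
        return None
    _, f, r = best
    vid = window.site.variant_id
    label = spec.mode.label
    pair_name = f"{vid}_{label}"
    return PrimerPair(
        pair_name=pair_name,
        fwd_name=f"{pair_name}_F",
        rev_name=f"{pair_name}_R",
        fwd_seq=f.seq,
        rev_seq=r.seq,
        fwd_tm=round(f.tm, 2),
        rev_tm=round(r.tm, 2),
        mode=spec.mode.name,
        predicted_product=r.end - f.start,
        amplicon_start=window.window_start + f.start,
        amplicon_end=window.window_start + r.end,
        chrom=window.site.chrom,
    )


def design_site(
    window: TemplateWindow,
    mode: DesignMode,
    params: EngineParams = EngineParams(),
) -> Optional[PrimerPair]:
    """One mode attempt for one site; infeasible windows count as failure."""
    try:
        spec = build_design_spec(window, mode, params)
    except DesignInfeasible as exc:
        logger.info("%s: %s", window.site.variant_id, exc)
        return None
    return design_pair(window, spec, params)


def waterfall_design(
    sites: list[TargetSite],
    reference,
    modes: Optional[dict[DesignModeName, DesignMode]] = None,
    params: EngineParams = EngineParams(),
    flank: int = 500,
    audit_records: Optional[list] = None,
) -> list[DesignOutcome]:
    """Run the TAS-opt → Relaxed-right → Relaxed-left waterfall.

    Every site gets exactly one :class:`DesignOutcome`; per-site errors
    (missing contig, short window) become per-site failures and never abort
    the batch. ``audit_records`` (if given) collects one machine-readable
    engine input record per site per attempted mode.
    """
    modes = modes or default_modes()
    outcomes = {id(s): DesignOutcome(site=s, pair=None) for s in sites}
    pending = list(sites)
    for mode_name in WATERFALL_ORDER:
        mode = modes[mode_name]
        still_pending: list[TargetSite] = []
        for site in pending:
            out = outcomes[id(site)]
            out.attempted_modes.append(mode_name)
            try:
                window = extract_window(reference, site, flank=flank)
                if audit_records is not None:
                    try:
                        spec = build_design_spec(window, mode, params)
                        audit_records.append(
                            spec.to_engine_record(site.variant_id, window.seq)
                        )
                    except DesignInfeasible:
                        pass
                pair = design_site(window, mode, params)
            except (KeyError, ValueError) as exc:
                logger.warning("%s: design failed (%s)", site.variant_id, exc)
                pair = None
            if pair is not None:
                out.pair = pair
            else:
                still_pending.append(site)
        pending = still_pending
        if not pending:
            break
    return [outcomes[id(s)] for s in sites]
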