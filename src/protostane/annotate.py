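"""Qualitative annotation of QTOF features of protostane triterpenoids.

The alisol family fragments in positive ESI almost exclusively by neutral
losses: successive/simultaneous loss of water (18 Da) and acetic acid
("HAc", 60 Da), plus side-chain losses (C4H8O, C4H10O2, C6H10O2, C6H12O3,
C2H2O) produced by dissociation of the C-23/C-24 bond.  Cleavage of that
bond leaves a skeleton ion whose m/z is diagnostic of the ring-system
oxidation pattern, and together with the UV absorption band (287 nm for the
11,12,13(17),16 conjugated systems, 245 nm for the 11,13(17) dienes, none
for unconjugated skeletons) it sorts the family into seven structural
types (I–VII).

This module implements that workflow on peak lists: explain each fragment as
a chain of neutral losses, assign the structural type from characteristic
skeleton ions + UV class, and identify features against a reference library
by retention time, accurate mass and expected fragments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .chem import (
    HYDROGEN_ATOM,
    AdductConvention,
    ElementalFormula,
    enumerate_formulas,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

__all__ = [
    "FragmentPeak",
    "FeatureRecord",
    "NeutralLoss",
    "DEFAULT_LOSS_VOCABULARY",
    "LossAnnotation",
    "TypeRule",
    "DEFAULT_TYPE_RULES",
    "LibraryEntry",
    "IdentificationResult",
    "AnnotationReport",
    "fragment_tolerance",
    "annotate_losses",
    "uv_class",
    "classify_type",
    "identify",
    "annotate_run",
]

# -- domain records ---------------------------------------------------------


@dataclass(frozen=True)
class FragmentPeak:
    """One product-ion peak (m/z, intensity)."""

    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.intensity < 0:
            raise ValueError("fragment intensity must be non-negative")


@dataclass(frozen=True)
class FeatureRecord:
    """One chromatographic feature: the input to annotation.

    ``uv_lambda_max`` is ``None`` when the feature has no UV maximum above
    200 nm (diode-array detectors cut off there).
    """

    retention_time: float
    precursor_mz: float
    fragments: tuple[FragmentPeak, ...] = ()
    uv_lambda_max: float | None = None
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError("retention time must be non-negative")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        # reporting convention: fragments sorted by m/z descending
        object.__setattr__(
            self, "fragments", tuple(sorted(self.fragments, key=lambda p: -p.mz))
        )


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral molecule lost between precursor and fragment."""

    label: str
    composition: ElementalFormula

    def __post_init__(self) -> None:
        if monoisotopic_mass(self.composition) <= 0:
            raise ValueError("neutral loss must have positive mass")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.composition)


def _loss(label: str, formula: str) -> NeutralLoss:
    return NeutralLoss(label, parse_formula(formula))


#: Losses observed in protostane spectra: water, acetic acid and the
#: C-23/C-24 side-chain fragments.
DEFAULT_LOSS_VOCABULARY: tuple[NeutralLoss, ...] = (
    _loss("H2O", "H2O"),
    _loss("HAc", "C2H4O2"),
    _loss("C2H2O", "C2H2O"),
    _loss("C4H8O", "C4H8O"),
    _loss("C4H10O2", "C4H10O2"),
    _loss("C6H10O2", "C6H10O2"),
    _loss("C6H12O3", "C6H12O3"),
)


@dataclass(frozen=True)
class LossAnnotation:
    """Explanation of one fragment as a chain of neutral losses.

    An empty ``loss_chain`` with ``matched=False`` means no chain within the
    configured depth and tolerance explains the fragment.
    """

    fragment_mz: float
    loss_chain: tuple[NeutralLoss, ...]
    ppm: float
    matched: bool

    @property
    def label(self) -> str:
        """Compact product-ion label, e.g. ``[M+H-HAc-H2O]+``."""
        if not self.matched:
            return "unassigned"
        if not self.loss_chain:
            return "[M+H]+"
        return "[M+H-" + "-".join(l.label for l in self.loss_chain) + "]+"


def fragment_tolerance(mz: float, tol_ppm: float = 15.0, floor_da: float = 0.003) -> float:
    """Absolute match window for a fragment: ppm tolerance with a mDa floor.

    QTOF product-ion accuracy is looser than MS1; the absolute floor keeps
    low-mass fragments from being held to sub-mDa windows.
    """
    return max(mz * tol_ppm * 1e-6, floor_da)


def annotate_losses(
    precursor_mz: float,
    fragments: list[FragmentPeak] | tuple[FragmentPeak, ...],
    losses: tuple[NeutralLoss, ...] = DEFAULT_LOSS_VOCABULARY,
    tol_ppm: float = 15.0,
    max_depth: int = 4,
    floor_da: float = 0.003,
) -> list[LossAnnotation]:
    """Explain each fragment by the shortest loss chain matching its mass gap.

    Chains are multisets of vocabulary losses up to ``max_depth`` deep; the
    chain whose cumulative mass equals ``precursor - fragment`` within the
    fragment tolerance wins.  Ties break by chain length, then |ppm|, then
    the lexicographic label chain, so output is deterministic.  A fragment at
    the precursor mass itself gets the empty chain.
    """
    if not losses:
        raise ValueError("loss vocabulary must not be empty")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    out = []
    for peak in fragments:
        out.append(_best_chain(precursor_mz, peak.mz, losses, tol_ppm, max_depth, floor_da))
    return out


def _chain_mass(chain) -> float:
    """Mass of a loss chain via its summed elemental composition.

    Summing counts first makes exactly mass-degenerate chains (for example
    C4H8O + H2O versus C4H10O2) bit-identical, so the length/|ppm|/label
    tie-break is deterministic instead of resting on float summation order.
    """
    total: dict[str, int] = {}
    for loss in chain:
        for elem, n in loss.composition.counts:
            total[elem] = total.get(elem, 0) + n
    return monoisotopic_mass(ElementalFormula.from_dict(total))


def _best_chain(
    precursor_mz: float,
    fragment_mz: float,
    losses: tuple[NeutralLoss, ...],
    tol_ppm: float,
    max_depth: int,
    floor_da: float,
) -> LossAnnotation:
    tol = fragment_tolerance(fragment_mz, tol_ppm, floor_da)
    best: tuple[int, float, tuple[str, ...]] | None = None
    best_chain: tuple[NeutralLoss, ...] = ()
    best_ppm = 0.0
    # depth-0 chain: fragment is the precursor itself
    for depth in range(0, max_depth + 1):
        for combo in itertools.combinations_with_replacement(losses, depth):
            expected = precursor_mz - _chain_mass(combo)
            if expected <= 0 or abs(fragment_mz - expected) > tol:
                continue
            ppm = (fragment_mz - expected) / expected * 1e6
            chain = tuple(sorted(combo, key=lambda l: l.label))
            key = (depth, abs(ppm), tuple(l.label for l in chain))
            if best is None or key < best:
                best, best_chain, best_ppm = key, chain, ppm
        if best is not None:
            break  # shortest chain wins: stop at the first depth with a hit
    if best is None:
        return LossAnnotation(fragment_mz, (), 0.0, matched=False)
    return LossAnnotation(fragment_mz, best_chain, best_ppm, matched=True)


# -- seven-type classification ----------------------------------------------


@dataclass(frozen=True)
class TypeRule:
    """Characteristic skeleton ion + UV class defining one structural type.

    The skeleton ion m/z values are the empirical values reported for the
    family (the instrumental fragment masses), not values recomputed from a
    nominal loss composition; fragment assignment of the skeleton ions is
    uncertain at the ~8 ppm level, so the empirical numbers are authoritative.
    """

    type_id: str
    characteristic_ion_mz: float
    uv_class: str  # one of {"287-band", "245-band", "none"}


#: Rules in evaluation order: the rarer/more specific skeleton ions first,
#: then the two UV-disambiguated pairs (VI/VII at 399.29, I/II at 397.27).
DEFAULT_TYPE_RULES: tuple[TypeRule, ...] = (
    TypeRule("IV", 339.2684, "none"),
    TypeRule("V", 385.3102, "none"),
    TypeRule("III", 383.2983, "none"),
    TypeRule("VI", 399.2896, "none"),
    TypeRule("VII", 399.2896, "245-band"),
    TypeRule("I", 397.2745, "287-band"),
    TypeRule("II", 397.2745, "245-band"),
)

_SHARED_ION_GROUPS = (("VI", "VII"), ("I", "II"))


def uv_class(lambda_max: float | None, window_nm: float = 5.0) -> str:
    """Bin a UV maximum into 287-band / 245-band / none."""
    if lambda_max is None:
        return "none"
    if abs(lambda_max - 287.0) <= window_nm:
        return "287-band"
    if abs(lambda_max - 245.0) <= window_nm:
        return "245-band"
    return "none"


def classify_type(
    feature: FeatureRecord,
    rules: tuple[TypeRule, ...] = DEFAULT_TYPE_RULES,
    tol_ppm: float = 15.0,
) -> str | None:
    """Assign a structural type from characteristic ions + UV class.

    A rule fires when some fragment matches its skeleton ion within
    ``tol_ppm`` AND the feature's UV class equals the rule's.  Rules are
    evaluated in the given order and the first UV-consistent hit wins; if a
    shared-ion pair (I/II or VI/VII) matches on the ion but neither member is
    UV-consistent, classification moves on and ultimately returns ``None``.
    """
    if not rules:
        raise ValueError("rule list must not be empty")
    feat_uv = uv_class(feature.uv_lambda_max)
    mzs = [p.mz for p in feature.fragments]
    for rule in rules:
        tol = rule.characteristic_ion_mz * tol_ppm * 1e-6
        ion_hit = any(abs(mz - rule.characteristic_ion_mz) <= tol for mz in mzs)
        if ion_hit and feat_uv == rule.uv_class:
            return rule.type_id
    return None


# -- library identification --------------------------------------------------


@dataclass(frozen=True)
class LibraryEntry:
    """One reference compound of the packaged 25-entry library."""

    peak: int
    name: str
    formula: ElementalFormula
    retention_time: float
    type_id: str
    standard_confirmed: bool
    quantified: bool
    expected_fragments: tuple[float, ...]
    expected_losses: tuple[tuple[str, ...], ...] = ()
    reported_precursor_mz: float | None = None
    reported_error_ppm: float | None = None
    uv_lambda_max: float | None = None
    mz_anomalous: bool = False


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of matching one feature against the library.

    ``mode`` is ``"standard-match"`` (retention time + fragment evidence
    against a standard-confirmed entry), ``"tentative"`` (library candidate
    or de novo formula without standard-level evidence) or
    ``"unidentified"``.
    """

    feature: FeatureRecord
    mode: str
    matched_entry: LibraryEntry | None = None
    assigned_formula: ElementalFormula | None = None
    assigned_type: str | None = None
    precursor_ppm: float | None = None
    fragment_hits: int = 0
    diagnostics: tuple[str, ...] = ()


def _count_fragment_hits(
    feature: FeatureRecord, expected: tuple[float, ...], tol_ppm: float, floor_da: float
) -> int:
    hits = 0
    for exp in expected:
        tol = fragment_tolerance(exp, tol_ppm, floor_da)
        if any(abs(p.mz - exp) <= tol for p in feature.fragments):
            hits += 1
    return hits


def identify(
    feature: FeatureRecord,
    library: tuple[LibraryEntry, ...] | list[LibraryEntry],
    rt_window: float = 0.5,
    ms1_tol_ppm: float = 5.0,
    min_fragment_hits: int = 2,
    fragment_tol_ppm: float = 15.0,
    fragment_floor_da: float = 0.003,
    conv: AdductConvention = HYDROGEN_ATOM,
    rules: tuple[TypeRule, ...] = DEFAULT_TYPE_RULES,
) -> IdentificationResult:
    """Identify one feature against the reference library.

    Candidates must co-elute (|Δt| ≤ ``rt_window``) and agree either on the
    precursor formula (within ``ms1_tol_ppm``) or on at least
    ``min_fragment_hits`` expected product ions; the best candidate is the
    one with the most fragment evidence.  A standard-confirmed candidate
    with sufficient fragment evidence gives a standard match; a precursor
    mass discrepancy is then recorded as a diagnostic rather than vetoing
    the retention-time + product-ion evidence.  Otherwise the feature is
    reported tentatively with the best candidate or, failing that, with a de
    novo formula from bounded enumeration; features explained by neither are
    unidentified.
    """
    if not library:
        raise ValueError("library must not be empty")
    candidates = []
    for entry in library:
        if abs(feature.retention_time - entry.retention_time) > rt_window:
            continue
        ppm = ppm_error(feature.precursor_mz, entry.formula, conv)
        formula_ok = abs(ppm) <= ms1_tol_ppm
        hits = _count_fragment_hits(
            feature, entry.expected_fragments, fragment_tol_ppm, fragment_floor_da
        )
        if formula_ok or hits >= min_fragment_hits:
            candidates.append((entry, ppm, formula_ok, hits))
    assigned_type = classify_type(feature, rules, fragment_tol_ppm)
    if candidates:
        candidates.sort(
            key=lambda c: (
                -c[3],  # fragment hits
                not c[2],  # formula agreement
                abs(c[1]),  # |ppm|
                abs(feature.retention_time - c[0].retention_time),
                c[0].peak,
            )
        )
        entry, ppm, formula_ok, hits = candidates[0]
        diagnostics = ()
        if not formula_ok:
            diagnostics = (
                f"precursor mass discrepancy: {ppm:+.1f} ppm vs {entry.formula}",
            )
        mode = (
            "standard-match"
            if entry.standard_confirmed and hits >= min_fragment_hits
            else "tentative"
        )
        return IdentificationResult(
            feature,
            mode,
            matched_entry=entry,
            assigned_formula=entry.formula,
            assigned_type=assigned_type if assigned_type else entry.type_id,
            precursor_ppm=ppm,
            fragment_hits=hits,
            diagnostics=diagnostics,
        )
    formulas = enumerate_formulas(feature.precursor_mz, ms1_tol_ppm, conv=conv)
    if formulas:
        f, ppm = formulas[0]
        return IdentificationResult(
            feature,
            "tentative",
            assigned_formula=f,
            assigned_type=assigned_type,
            precursor_ppm=ppm,
        )
    return IdentificationResult(feature, "unidentified", assigned_type=assigned_type)


# -- batch driver ------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationReport:
    """Per-feature identifications plus summary tallies."""

    results: tuple[IdentificationResult, ...]

    @property
    def n_features(self) -> int:
        return len(self.results)

    @property
    def n_identified(self) -> int:
        return sum(1 for r in self.results if r.mode != "unidentified")

    @property
    def n_standard_matches(self) -> int:
        return sum(1 for r in self.results if r.mode == "standard-match")

    @property
    def type_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for r in self.results:
            if r.assigned_type:
                tally[r.assigned_type] = tally.get(r.assigned_type, 0) + 1
        return dict(sorted(tally.items()))

    def summary(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_identified": self.n_identified,
            "n_standard_matches": self.n_standard_matches,
            "type_tally": self.type_tally,
        }


def annotate_run(
    features: list[FeatureRecord] | tuple[FeatureRecord, ...],
    library: tuple[LibraryEntry, ...] | list[LibraryEntry],
    **identify_kwargs,
) -> AnnotationReport:
    """Identify every feature in a run and tally the outcome."""
    results = tuple(identify(f, library, **identify_kwargs) for f in features)
    return AnnotationReport(results)
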