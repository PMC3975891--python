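"""Per-element decision tree, site assignment and bookkeeping.

For every flagged water, each candidate element is pushed through a
fixed sequence of chemical and physical checks: donor identity ->
coordination number -> geometry -> bond-valence window -> VECSUM ->
f'' consistency -> electron-count consistency. The strict variant
applies all of them; the weak variant (used only when a heavy-looking
site fails every candidate and waivers are enabled) drops the tests
that demand a complete, well-ordered shell: geometry and VECSUM are
waived, the coordination minimum is relaxed by two and the bond-valence
window widens from +/-0.25 to +/-0.5 valence units around the formal
charge. Chloride is judged by its own rule: a positively polarized
environment (amide N, Arg/Lys/His/Asn/Gln side-chain N, or a modeled
cation) instead of the cation donor rules.

A unique passing candidate is assigned; multiple viable candidates
yield an ambiguity record ranked by f'' consistency, then bond-valence
deviation, then geometry; a heavy-looking site with no viable element
is reported as an unknown heavier scatterer and left as water.

After assignment the occupancy is reset to 1.0 (or the special-position
fraction), the B factor to the solvent mean, and the ADP mode follows
the resolution rule: anisotropic below 1.5 A, or above 2.5 A for
elements at least as heavy as potassium.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as _params
from .config import RunConfig
from .environment import (CoordinationShell, GeometryAssessment, build_shell,
                          classify_geometry, halide_partner, _donor_context)
from .screening import (HEAVY_CANDIDATE, LIGHT_CANDIDATE, PLAIN_WATER, REJECTED,
                        ScreenVerdict, SiteFeatures, combine_with_environment,
                        density_support_map, features_for, screen_site)
from .structure import AtomSite, Model, special_position_multiplicity
from .valence import valence_analysis

log = logging.getLogger(__name__)

__all__ = [
    "CandidateResult", "IonDecision", "PipelineResult", "ValidationRecord",
    "evaluate_candidate", "decide_site", "bookkeeping", "adp_rule",
    "resolution_gate", "run_pipeline", "write_converted_model",
    "KEEP_WATER", "ASSIGN", "AMBIGUOUS", "HEAVY_UNKNOWN",
]

KEEP_WATER = "keep_water"
ASSIGN = "assign"
AMBIGUOUS = "ambiguous"
HEAVY_UNKNOWN = "heavy_unknown"

STRICT = "strict"
WEAK = "weak"


@dataclass
class CandidateResult:
    """Pass/fail ledger for one candidate element at one site."""

    element: str
    passed_strict: bool = False
    passed_weak: bool = False
    reject_reasons: list[str] = field(default_factory=list)  # weak-mode failures
    strict_only_failures: list[str] = field(default_factory=list)
    bvs: float = 0.0
    vecsum: float = 0.0
    bvs_window: tuple[float, float] = (0.0, 0.0)
    fpp_consistent: str = "not_measured"  # yes / no / not_measured
    geometry_ok: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "element": self.element,
            "passed_strict": self.passed_strict,
            "passed_weak": self.passed_weak,
            "reject_reasons": list(self.reject_reasons),
            "strict_only_failures": list(self.strict_only_failures),
            "bvs": round(self.bvs, 4),
            "vecsum": round(self.vecsum, 4),
            "bvs_window": [round(x, 4) for x in self.bvs_window],
            "fpp_consistent": self.fpp_consistent,
            "geometry_ok": self.geometry_ok,
            "notes": list(self.notes),
        }


@dataclass
class IonDecision:
    """Final outcome for one water site."""

    site_id: str
    status: str
    element: str | None = None
    alternatives: list[CandidateResult] = field(default_factory=list)
    triggers: list[str] = field(default_factory=list)
    bookkeeping: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site": self.site_id,
            "status": self.status,
            "element": self.element,
            "triggers": list(self.triggers),
            "alternatives": [c.to_dict() for c in self.alternatives],
            "bookkeeping": dict(self.bookkeeping),
            "notes": list(self.notes),
        }


def _strict_window(profile, cfg: RunConfig) -> tuple[float, float]:
    q = abs(profile.formal_charge)
    return (q - cfg.bvs_window_strict, q + cfg.bvs_window_strict)


def _weak_window(profile, cfg: RunConfig) -> tuple[float, float]:
    if cfg.require_valence:
        return _strict_window(profile, cfg)
    q = abs(profile.formal_charge)
    return (q - cfg.bvs_window_weak, q + cfg.bvs_window_weak)


def evaluate_candidate(
    element: str,
    shell: CoordinationShell,
    geometry: GeometryAssessment | None,
    features: SiteFeatures,
    config: RunConfig | None = None,
    verdict: ScreenVerdict | None = None,
) -> CandidateResult:
    """Run the per-element filter chain for one candidate at one site.

    Both strictness levels are evaluated in one pass; every weak-mode
    failure is appended to ``reject_reasons`` and strict-only failures
    (tests the waiver may drop) are kept separately.
    """
    cfg = config or RunConfig()
    element = element.upper()
    profile = _params.get_profile(element)
    if geometry is None:
        geometry = classify_geometry(shell, rmsd_threshold=cfg.geometry_rmsd_max)
    res = CandidateResult(element=element)
    weak_fail = res.reject_reasons
    strict_fail = res.strict_only_failures

    occupancy = features.occupancy if features.occupancy else shell.center.occupancy
    occupancy = occupancy if occupancy and occupancy > 0 else 1.0
    val = valence_analysis(shell.donors, element, occupancy=occupancy)
    res.bvs, res.vecsum = val.bvs, val.vecsum
    res.notes.extend(val.warnings)

    if element == "CL":
        _evaluate_halide(res, profile, shell, cfg)
    else:
        _evaluate_cation(res, profile, shell, geometry, cfg)

    # f'' consistency (applies to every element when measured)
    _check_fpp(res, profile, features, cfg)

    # electron-count consistency against the density triggers
    if verdict is not None:
        if profile.weight_class == "heavy" and verdict.status != HEAVY_CANDIDATE:
            weak_fail.append("density_consistency")
        if (profile.weight_class == "light" and features.peak_fofc is not None
                and features.peak_fofc > cfg.fofc_cutoff):
            weak_fail.append("density_consistency")

    res.passed_weak = not weak_fail
    res.passed_strict = res.passed_weak and not strict_fail
    return res


def _evaluate_cation(res: CandidateResult, profile, shell: CoordinationShell,
                     geometry: GeometryAssessment, cfg: RunConfig) -> None:
    weak_fail, strict_fail = res.reject_reasons, res.strict_only_failures

    # 1. donor identity (incl. thiolate/thioether restrictions)
    for c in shell.donors:
        ctx = _donor_context(c)
        if not profile.allows_donor(c.atom.element, ctx):
            weak_fail.append("donor_identity")
            res.notes.append(
                f"donor {c.atom.id.short()} ({c.atom.element}:{ctx}) "
                f"not allowed for {profile.element}")
            break
    if shell.has_disqualifying_contact():
        weak_fail.append("close_nonpolar_contact")

    # 2. coordination number
    lo, hi = profile.coordination_range
    n = len(shell.donors)
    if not lo <= n <= hi:
        weak_lo = max(1, lo - 2)
        if weak_lo <= n <= hi:
            strict_fail.append("coordination_number")
        else:
            weak_fail.append("coordination_number")

    # 3. geometry requirement (strict only; waived for heavy ions)
    if profile.required_geometry != "any":
        ok = (geometry.name == profile.required_geometry
              and geometry.angle_rmsd <= cfg.geometry_rmsd_max)
        # a one-vertex-short octahedron classifies as square pyramidal
        if (not ok and profile.required_geometry == "octahedral"
                and geometry.n_donors == 5 and geometry.name == "square_pyramidal"
                and geometry.angle_rmsd <= cfg.geometry_rmsd_max):
            ok = True
            res.notes.append("octahedron with one unresolved vertex")
        res.geometry_ok = ok
        if not ok:
            strict_fail.append("geometry")

    # 4. bond-valence window
    res.bvs_window = _strict_window(profile, cfg)
    lo_s, hi_s = res.bvs_window
    lo_w, hi_w = _weak_window(profile, cfg)
    if not lo_w <= res.bvs <= hi_w:
        weak_fail.append("bvs_window")
    elif not lo_s <= res.bvs <= hi_s:
        strict_fail.append("bvs_window")

    # 5. VECSUM (strict only)
    if res.vecsum > cfg.vecsum_max:
        strict_fail.append("vecsum")


def _evaluate_halide(res: CandidateResult, profile, shell: CoordinationShell,
                     cfg: RunConfig) -> None:
    """Chloride is identified by its positively polarized environment."""
    weak_fail = res.reject_reasons
    if not shell.motifs.get("amide_cation_environment"):
        weak_fail.append("halide_environment")
    pool = shell.donors + [c for c, _ in shell.excluded if _ == "metal_contact"] + shell.outer
    n_positive = sum(1 for c in pool
                     if c.distance <= cfg.halide_radius and halide_partner(c))
    lo, hi = profile.coordination_range
    if not lo <= n_positive <= hi:
        weak_fail.append("coordination_number")
    res.bvs_window = (float("nan"), float("nan"))
    res.notes.append(f"halide rule: {n_positive} positively polarized contacts")


def _check_fpp(res: CandidateResult, profile, features: SiteFeatures,
               cfg: RunConfig) -> None:
    weak_fail = res.reject_reasons
    fpp = features.fpp_refined
    wl = features.wavelength
    if fpp is None or wl is None:
        res.fpp_consistent = "not_measured"
    else:
        expected = _params.expected_fpp(profile.element, wl)
        if expected >= cfg.fpp_negligible:
            lo, hi = cfg.fpp_band
            ok = lo * expected <= fpp <= hi * expected
        else:
            # no anomalous signal expected: a substantial refined f'' rules it out
            ok = fpp <= 0.5
        res.fpp_consistent = "yes" if ok else "no"
        if not ok:
            weak_fail.append("fpp_mismatch")
    if (features.peak_anom is not None and features.peak_anom > cfg.anom_cutoff
            and wl is not None
            and _params.expected_fpp(profile.element, wl) < cfg.fpp_negligible):
        weak_fail.append("anomalous_inconsistent")


# ---------------------------------------------------------------------------
# site-level decision


def _rank_key(c: CandidateResult):
    fpp_rank = {"yes": 0, "not_measured": 1, "no": 2}[c.fpp_consistent]
    profile = _params.get_profile(c.element)
    bvs_dev = abs(c.bvs - abs(profile.formal_charge)) if c.element != "CL" else 0.0
    return (fpp_rank, bvs_dev, 0.0 if c.geometry_ok else 1.0, c.element)


def decide_site(
    verdict: ScreenVerdict,
    shell: CoordinationShell,
    geometry: GeometryAssessment | None,
    features: SiteFeatures,
    candidates: tuple[str, ...] | None = None,
    config: RunConfig | None = None,
) -> IonDecision:
    """Walk the decision tree for one screened water site."""
    cfg = config or RunConfig()
    candidates = tuple(candidates or cfg.candidates)
    site_id = shell.center.id.short()
    decision = IonDecision(site_id=site_id, status=KEEP_WATER,
                           triggers=list(verdict.triggers))

    if verdict.status == REJECTED:
        decision.notes.append("site rejected as unreliable; kept as water")
        return decision
    if verdict.status == PLAIN_WATER:
        return decision

    if geometry is None:
        geometry = classify_geometry(shell, rmsd_threshold=cfg.geometry_rmsd_max)
    results = [evaluate_candidate(e, shell, geometry, features, cfg, verdict)
               for e in candidates]
    strict_pass = sorted((r for r in results if r.passed_strict), key=_rank_key)

    if len(strict_pass) == 1:
        decision.status = ASSIGN
        decision.element = strict_pass[0].element
        decision.alternatives = strict_pass + sorted(
            (r for r in results if not r.passed_strict), key=_rank_key)
        return decision
    if len(strict_pass) >= 2:
        return _ambiguous(decision, strict_pass, results, features, cfg)

    # no strict pass: waiver path for heavy-looking sites
    if verdict.status == HEAVY_CANDIDATE:
        if cfg.allow_waiver:
            weak_pass = sorted((r for r in results if r.passed_weak), key=_rank_key)
            if len(weak_pass) == 1:
                decision.status = ASSIGN
                decision.element = weak_pass[0].element
                decision.notes.append("strict-only tests waived (heavy site)")
                decision.alternatives = weak_pass + sorted(
                    (r for r in results if not r.passed_weak), key=_rank_key)
                return decision
            if len(weak_pass) >= 2:
                return _ambiguous(decision, weak_pass, results, features, cfg,
                                  waived=True)
        decision.status = HEAVY_UNKNOWN
        decision.alternatives = sorted(results, key=_rank_key)
        decision.notes.append(
            "heavy scatterer indicated but every candidate element was rejected; "
            "site left as water")
        return decision

    # light-looking site with no viable candidate: keep the water
    decision.alternatives = sorted(results, key=_rank_key)
    return decision


def _ambiguous(decision: IonDecision, viable, results, features, cfg,
               waived: bool = False) -> IonDecision:
    decision.status = AMBIGUOUS
    decision.alternatives = viable + sorted(
        (r for r in results if r not in viable), key=_rank_key)
    if waived:
        decision.notes.append("strict-only tests waived (heavy site)")
    decision.notes.append(
        "multiple viable candidates: " + ", ".join(r.element for r in viable))
    if features.wavelength is not None and len(viable) >= 2:
        fpps = [_params.expected_fpp(r.element, features.wavelength) for r in viable[:2]]
        if abs(fpps[0] - fpps[1]) < 0.2:
            decision.notes.append(
                f"anomalous scattering does not discriminate "
                f"{viable[0].element} from {viable[1].element} at "
                f"{features.wavelength:.4f} A (f'' {fpps[0]:.2f} vs {fpps[1]:.2f} e-)")
    return decision


# ---------------------------------------------------------------------------
# bookkeeping

def adp_rule(resolution: float, element: str) -> str:
    """ADP mode for a newly placed ion.

    Anisotropic when the resolution is better than 1.5 A, or when it is
    worse than 2.5 A and the element is at least as heavy as potassium
    (Z >= 19); isotropic otherwise.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    z = _params.atomic_number(element)
    if resolution < 1.5 or (resolution > 2.5 and z >= 19):
        return "anisotropic"
    return "isotropic"


def resolution_gate(resolution: float | None, config: RunConfig | None = None) -> str | None:
    """Warning string when the data are too poor for reliable water picking."""
    cfg = config or RunConfig()
    if resolution is not None and resolution > cfg.resolution_warn:
        return (f"resolution {resolution:.2f} A is worse than {cfg.resolution_warn} A: "
                f"water picking and ion identification are unreliable at this "
                f"resolution; review all assignments manually")
    return None


def bookkeeping(decision: IonDecision, model: Model, solvent_b_mean: float | None,
                resolution: float | None, config: RunConfig | None = None) -> IonDecision:
    """Fill occupancy/B-factor/ADP bookkeeping for an assigned site."""
    if decision.status != ASSIGN:
        return decision
    cfg = config or RunConfig()
    site = None
    # locate the center from the site id recorded at decision time
    for w in model.atoms:
        if w.id.short() == decision.site_id:
            site = w
            break
    new_occ = 1.0
    if site is not None and model.has_symmetry:
        new_occ = special_position_multiplicity(model, site.xyz,
                                                tolerance=cfg.special_position_tol)
    decision.bookkeeping = {
        "new_occupancy": new_occ,
        "new_b_iso": solvent_b_mean,
        "adp_mode": (adp_rule(resolution, decision.element)
                     if resolution else "isotropic"),
    }
    return decision


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class ValidationRecord:
    """Post-hoc validation of an already-modeled ion (never modified)."""

    site_id: str
    element: str
    suspicious: bool
    result: CandidateResult

    def to_dict(self) -> dict:
        return {"site": self.site_id, "element": self.element,
                "suspicious": self.suspicious, "result": self.result.to_dict()}


@dataclass
class PipelineResult:
    decisions: list[IonDecision] = field(default_factory=list)
    validations: list[ValidationRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        return {
            "warnings": list(self.warnings),
            "decisions": [d.to_dict() for d in self.decisions],
            "validations": [v.to_dict() for v in self.validations],
            "config": self.config.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary_table(self) -> str:
        lines = [f"{'site':<24} {'status':<14} {'element':<8} triggers"]
        for d in self.decisions:
            lines.append(f"{d.site_id:<24} {d.status:<14} {d.element or '-':<8} "
                         f"{','.join(d.triggers) or '-'}")
        for v in self.validations:
            flag = "SUSPICIOUS" if v.suspicious else "ok"
            lines.append(f"{v.site_id:<24} {'validated':<14} {v.element:<8} {flag}")
        if self.warnings:
            lines.append("")
            lines.extend(f"WARNING: {w}" for w in self.warnings)
        return "\n".join(lines)


def run_pipeline(model: Model, features_table: pd.DataFrame | None = None,
                 config: RunConfig | None = None) -> PipelineResult:
    """Screen and classify every water in the model.

    Already-built ions are re-validated (and flagged when suspicious)
    but never changed. Output ordering is deterministic (by site id).
    """
    cfg = config or RunConfig()
    result = PipelineResult(config=cfg)
    result.warnings.extend(model.warnings)
    gate = resolution_gate(model.resolution, cfg)
    if gate:
        result.warnings.append(gate)

    waters = sorted(model.waters(), key=lambda a: a.id.short())
    solvent_b = float(np.mean([w.b_iso for w in waters])) if waters else None
    support = density_support_map(features_table)

    for water in waters:
        feats = features_for(features_table, water.id)
        if feats.b_iso is None:
            feats.b_iso = water.b_iso
        if feats.occupancy is None:
            feats.occupancy = water.occupancy
        if feats.solvent_b_mean is None:
            feats.solvent_b_mean = solvent_b
        if feats.wavelength is None:
            feats.wavelength = cfg.wavelength
        verdict = screen_site(feats, cfg)
        shell = build_shell(water, model, radius=cfg.shell_radius,
                            density_support=support,
                            density_threshold=cfg.donor_density_min,
                            halide_radius=cfg.halide_radius,
                            close_oo_cutoff=cfg.close_oo_cutoff)
        verdict = combine_with_environment(verdict, shell)
        if verdict.status in (REJECTED, PLAIN_WATER):
            decision = decide_site(verdict, shell, None, feats,
                                   cfg.candidates, cfg)
        else:
            geometry = classify_geometry(shell, rmsd_threshold=cfg.geometry_rmsd_max)
            decision = decide_site(verdict, shell, geometry, feats,
                                   cfg.candidates, cfg)
            bookkeeping(decision, model, solvent_b, model.resolution, cfg)
        result.decisions.append(decision)

    for ion in sorted(model.modeled_ions(), key=lambda a: a.id.short()):
        if ion.element not in _params.SUPPORTED_ELEMENTS:
            continue
        feats = features_for(features_table, ion.id)
        if feats.occupancy is None:
            feats.occupancy = ion.occupancy
        shell = build_shell(ion, model, radius=cfg.shell_radius,
                            density_support=support,
                            density_threshold=cfg.donor_density_min)
        res = evaluate_candidate(ion.element, shell, None, feats, cfg)
        result.validations.append(ValidationRecord(
            site_id=ion.id.short(), element=ion.element,
            suspicious=not res.passed_weak, result=res))
    return result


def write_converted_model(model: Model, result: PipelineResult, path) -> None:
    """Emit a copy of the model with assigned waters converted to ions.

    Residue and atom names are changed to the element symbol and the
    occupancy/B factor follow the bookkeeping. The input model is never
    modified in place, and no refinement is performed.
    """
    import gemmi

    st = model.structure.clone()
    assigned = {d.site_id: d for d in result.decisions if d.status == ASSIGN}
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                aid_short = (f"{chain.name}/{residue.name.strip()}{residue.seqid.num}"
                             f"{(residue.seqid.icode or ' ').strip()}/{atom.name}"
                             + (f".{atom.altloc}" if atom.altloc.strip(chr(0)) else ""))
                d = assigned.get(aid_short)
                if d is None:
                    continue
                residue.name = d.element
                atom.name = d.element
                atom.element = gemmi.Element(d.element.capitalize())
                atom.occ = float(d.bookkeeping.get("new_occupancy", 1.0))
                if d.bookkeeping.get("new_b_iso") is not None:
                    atom.b_iso = float(d.bookkeeping["new_b_iso"])
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
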