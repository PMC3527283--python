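"""End-to-end six-phase breakpoint delineation pipeline.

Per mutant allele:

1. PCR tiling scan over the region of interest, then interval inference
   (minimal / maximal deletion intervals from informative primers).
2. In-silico "blot": a probe window just south of the deletion is chosen by
   binary search on probe presence in the mutant, then restriction enzymes
   are screened for an RFLP at that probe.
3. The mutant junction fragment is circularized and an inverse-PCR product
   is predicted from outward-facing primers in the probe region.
4. The junction-spanning part of that product is mapped back to the
   reference: breakpoints, deletion size, filler, microhomology.
5. Validation primers flanking the junction are designed and the predicted
   cross-junction product is checked base-for-base.
6. Donor windows around each breakpoint are scanned for A/T content,
   tandem repeats, hairpin-capable inverted repeats and MAR propensity.

Alleles whose north flank is repetitive complete phases 1-4 with the north
side unmappable; the pipeline records the limitation (and the phase-1 lower
bound on deletion size that is still available) instead of failing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._seq import revcomp
from .errors import BreakscanError, DataError, NoJunctionError, PhaseError
from .features import (
    at_content_windows,
    find_inverted_repeats,
    find_tandem_repeats,
    mar_propensity,
    merge_candidate_regions,
)
from .genome import Genome, PrimerPair
from .intervals import DeletionInterval, infer_deletion_interval
from .junction import (
    JunctionCall,
    classify_repair,
    design_validation_primers,
    extract_donors,
    locate_filler_origin,
    map_junction,
    validate_junction,
)
from .pcr import AmpliconMatrix, build_amplicon_matrix
from .rflp import BUILTIN_ENZYMES, digest, find_rflp, ipcr_predict
from . import io as bsio


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run; every default is scale-aware via
    :meth:`scaled_defaults`."""

    seed: int = 0
    max_product: int = 5_000
    min_anchor: int = 20
    window: int = 50
    threshold: float = 0.75
    flank: int = 1_000
    mh_threshold: int = 2
    target_size: int = 800
    probe_width: int = 2_000
    read_length: int = 800  # usable junction sequence off the iPCR product
    out_dir: str | None = None

    @classmethod
    def scaled_defaults(cls, **overrides) -> "PipelineConfig":
        base = dict(flank=300, probe_width=400, target_size=500, read_length=380)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key=value config file; CLI overrides win over file values."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise DataError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise DataError(f"{path}:{lineno}: unknown key {key!r}")
                if key == "out_dir":
                    values[key] = raw
                elif key == "threshold":
                    values[key] = float(raw)
                else:
                    values[key] = int(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


@dataclass
class AlleleReport:
    allele: str
    phases: dict = field(default_factory=dict)
    limitations: list[str] = field(default_factory=list)
    failed_phase: str | None = None
    failure_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "phases": self.phases,
            "limitations": self.limitations,
            "failed_phase": self.failed_phase,
            "failure_reason": self.failure_reason,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    parent_label: str
    matrix: AmpliconMatrix
    intervals: dict[str, DeletionInterval]
    calls: dict[str, JunctionCall]
    reports: dict[str, AlleleReport]

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
            "parent": self.parent_label,
            "alleles": {k: r.to_dict() for k, r in sorted(self.reports.items())},
        }


def _south_boundary_search(
    parent: Genome, mutant: Genome, lo: int, hi: int, width: int
) -> int:
    """Smallest b in [lo, hi] whose parent window [b, b+width-1] occurs in
    the mutant; with a contiguous deletion and unique windows this is the
    first retained south base (the in-silico analogue of iterative probe
    hybridization)."""
    hi = min(hi, len(parent) - width + 1)
    mseq = mutant.sequence

    def present(b: int) -> bool:
        return mseq.find(parent.sub(b, b + width - 1)) != -1

    if present(lo) or not present(hi):
        raise PhaseError("probe search bounds do not bracket the junction")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if present(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _feature_summary(seq: str, config: PipelineConfig) -> dict:
    windows = at_content_windows(seq, window=config.window, threshold=config.threshold)
    mar = mar_propensity(seq) if len(seq) >= 300 else []
    return {
        "length": len(seq),
        "at_fraction_mean": round(
            sum(w.at_fraction for w in windows) / len(windows), 4
        ),
        "n_windows_flagged": sum(w.flagged for w in windows),
        "tandem_repeats": [
            dataclasses.asdict(r) for r in find_tandem_repeats(seq)[:10]
        ],
        "hairpins": [
            dataclasses.asdict(h) for h in find_inverted_repeats(seq)[:5]
        ],
        "mar_regions": merge_candidate_regions(mar),
    }


def run_allele(
    reference: Genome,
    mutant: Genome,
    matrix: AmpliconMatrix,
    config: PipelineConfig,
    decoys: list[Genome] = (),
) -> tuple[AlleleReport, DeletionInterval | None, JunctionCall | None]:
    """Run phases 1-6 for a single allele; failures are recorded, not raised."""
    allele = mutant.name
    report = AlleleReport(allele)
    interval: DeletionInterval | None = None
    call: JunctionCall | None = None
    try:
        # phase 1 -- delineation from the amplicon matrix
        interval = infer_deletion_interval(
            matrix, allele, matrix.parent_label, len(reference)
        )
        report.phases["phase1_interval"] = {
            "inner": interval.inner,
            "outer": interval.outer,
            "min_size": interval.min_size,
            "max_size": interval.max_size,
            "n_informative": interval.n_informative,
            "note": interval.note,
        }
        if interval.inner is None:
            raise PhaseError("no deletion evidence in the amplicon matrix")

        # phase 2 -- in-silico blot: probe placement and RFLP screen
        lo = interval.inner[0]
        hi = min(interval.outer[1], len(reference))
        boundary = _south_boundary_search(
            reference, mutant, lo, hi, config.probe_width
        )
        probe_start = min(boundary + 50, len(reference) - config.probe_width + 1)
        probe = (probe_start, probe_start + config.probe_width - 1)
        rflp_hits = find_rflp(reference, mutant, BUILTIN_ENZYMES, probe)
        if not rflp_hits:
            raise PhaseError("no RFLP-positive enzyme at the probe")
        report.phases["phase2_rflp"] = {
            "probe": probe,
            "hits": [
                {
                    "enzyme": h.enzyme.name,
                    "parent_sizes": list(h.parent_sizes),
                    "mutant_sizes": list(h.mutant_sizes),
                }
                for h in rflp_hits[:5]
            ],
        }

        # phases 3-4 -- iPCR product, then junction mapping; if the chosen
        # fragment leaves the junction too close to a cut site, fall through
        # to the next RFLP-positive enzyme
        probe_m0 = mutant.sequence.find(reference.sub(*probe))
        if probe_m0 == -1:
            raise PhaseError("probe sequence missing from mutant")
        pm = probe_m0 + 1
        last_error = "no usable junction fragment"
        fallback: tuple[JunctionCall, dict] | None = None
        for hit in rflp_hits:
            if hit.smallest_mutant is None:
                continue
            frag = digest(mutant, hit.enzyme).containing(pm)
            if frag.end < pm + 79:
                continue  # outward primer pair does not fit in the fragment
            rev_site = (pm + 20, pm + 39)
            fwd_site = (pm + 60, pm + 79)
            pair = PrimerPair(
                f"ipcr-{allele}",
                fwd=mutant.sub(*fwd_site),
                rev=revcomp(mutant.sub(*rev_site)),
            )
            product = ipcr_predict(frag.sequence, pair)
            if not product or not product.spans_ligation:
                last_error = "iPCR primers did not converge across the ligation"
                continue
            # split the product at the known ligation seam: everything after
            # it is the contiguous mutant segment [frag.start .. rev_site end]
            seam = frag.end - fwd_site[0] + 1
            junction_read = product.sequence[seam:]
            # a sequencing read off the rev primer covers a bounded stretch;
            # keep the primer-proximal tail of the fragment arc
            junction_read = junction_read[-config.read_length :]
            if len(junction_read) < 2 * config.min_anchor:
                last_error = "junction read too short"
                continue
            try:
                call = map_junction(
                    junction_read, reference, config.min_anchor, allele=allele
                )
            except NoJunctionError:
                last_error = "no junction in the iPCR read"
                call = None
                continue
            phase3 = {
                "enzyme": hit.enzyme.name,
                "fragment": (frag.start, frag.end),
                "fragment_size": frag.size,
                "product_size": len(product.sequence),
            }
            if call.north_mappable and call.south_mappable:
                report.phases["phase3_ipcr"] = phase3
                break
            # a cut site close to the junction can truncate one anchor; keep
            # the one-sided call but let another enzyme try to resolve it
            if fallback is None:
                fallback = (call, phase3)
            call = None
        if call is None and fallback is not None:
            call, phase3 = fallback
            report.phases["phase3_ipcr"] = phase3
        if call is None:
            raise PhaseError(last_error)
        report.phases["phase4_junction"] = call.to_dict()

        # a repetitive north flank leaves only the phase-1 lower bound
        if not call.north_mappable:
            report.limitations.append("north side unmappable")
            if call.south_mappable and interval.outer[0] > 0:
                bound = call.south_bp - interval.outer[0]
                report.phases["min_deletion_bound"] = {
                    "bp": bound,
                    "kbp": round(bound / 1000, 3),
                    "from": "south breakpoint minus nearest informative "
                    "PCR-positive amplicon end on the north side",
                }
        if not call.south_mappable:
            report.limitations.append("south side unmappable")

        if call.north_mappable and call.south_mappable:
            classify_repair(call, config.mh_threshold)
            report.phases["phase4_junction"] = call.to_dict()

            # phase 5 -- cross-junction validation
            pair = design_validation_primers(
                call, reference, mutant, target_size=config.target_size
            )
            result = validate_junction(
                mutant, pair, call, reference, max_product=config.max_product
            )
            report.phases["phase5_validation"] = {
                "primer_fwd": pair.fwd,
                "primer_rev": pair.rev,
                "passed": result.passed,
                "product_size": len(result.product),
                "reason": result.reason,
            }
            if not result.passed:
                report.failed_phase = "phase5_validation"
                raise PhaseError(f"phase 5 validation failed: {result.reason}")

            # phase 6 -- junction feature analyses on donor windows
            donors = extract_donors(reference, call, flank=config.flank)
            report.phases["phase6_features"] = {
                "north_donor": _feature_summary(donors.north_donor, config),
                "south_donor": _feature_summary(donors.south_donor, config),
                "donor_notes": donors.notes,
            }
            if call.filler and len(call.filler) >= 10 and decoys:
                hits = locate_filler_origin(call.filler, list(decoys))
                report.phases["phase6_filler_origin"] = [
                    dataclasses.asdict(h) for h in hits[:5]
                ]
        else:
            # phase 6 on whichever side is anchored
            side = "south" if call.south_mappable else "north"
            pos = call.south_bp if call.south_mappable else call.north_bp
            lo_w = max(1, pos - config.flank)
            hi_w = min(len(reference), pos + config.flank - 1)
            report.phases["phase6_features"] = {
                f"{side}_flank": _feature_summary(reference.sub(lo_w, hi_w), config)
            }
    except BreakscanError as exc:
        report.failed_phase = report.failed_phase or _phase_of(report)
        report.failure_reason = str(exc)
    return report, interval, call


def _phase_of(report: AlleleReport) -> str:
    """First phase without a recorded entry (= the phase that failed)."""
    order = [
        "phase1_interval",
        "phase2_rflp",
        "phase3_ipcr",
        "phase4_junction",
        "phase5_validation",
        "phase6_features",
    ]
    done = set(report.phases)
    for name in order:
        if name not in done:
            return name
    return "post"


def run_pipeline(
    reference: Genome,
    mutants: list[Genome],
    panel: list[PrimerPair],
    config: PipelineConfig,
    decoys: list[Genome] = (),
) -> PipelineResult:
    """Phases 1-6 for every mutant against one parent reference."""
    matrix = build_amplicon_matrix(
        [reference, *mutants], panel, reference.name, config.max_product
    )
    intervals: dict[str, DeletionInterval] = {}
    calls: dict[str, JunctionCall] = {}
    reports: dict[str, AlleleReport] = {}
    for mutant in mutants:
        report, interval, call = run_allele(
            reference, mutant, matrix, config, decoys=decoys
        )
        reports[mutant.name] = report
        if interval is not None:
            intervals[mutant.name] = interval
        if call is not None:
            calls[mutant.name] = call
    return PipelineResult(config, reference.name, matrix, intervals, calls, reports)


def render_report(result: PipelineResult, outdir: str | Path) -> dict:
    """Write the structured report (JSON) and a human-readable summary.

    Deterministic: ordering is sorted, and re-rendering the same result
    produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    bsio.write_json(outdir / "report.json", payload)
    result.matrix.to_tsv(outdir / "amplicon_matrix.tsv")
    lines = [
        f"breakscan {__version__} pipeline report",
        f"parent: {result.parent_label}  seed: {result.config.seed}",
        "",
    ]
    for name in sorted(result.reports):
        rep = result.reports[name]
        call = result.calls.get(name)
        lines.append(f"== {name} ==")
        if call and call.north_mappable and call.south_mappable:
            lines.append(
                f"  junction: north_bp={call.north_bp} south_bp={call.south_bp} "
                f"deletion={call.deletion_size} bp filler={call.filler or '-'} "
                f"microhomology={call.microhomology or '-'} "
                f"repair={','.join(sorted(call.repair_flags)) or '-'}"
            )
        elif call:
            known = (
                f"south_bp={call.south_bp}"
                if call.south_mappable
                else f"north_bp={call.north_bp}"
            )
            lines.append(f"  junction: {known}; {'; '.join(rep.limitations)}")
            bound = rep.phases.get("min_deletion_bound")
            if bound:
                lines.append(f"  minimal deletion: >= {bound['kbp']} kbp")
        if rep.failure_reason:
            lines.append(f"  FAILED at {rep.failed_phase}: {rep.failure_reason}")
        lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines))
    return payload
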