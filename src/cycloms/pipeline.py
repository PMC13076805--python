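"""End-to-end orchestration of the discovery pipeline.

Runs, as requested by the inputs present: MS1 fingerprinting →
dereplication of candidates → digestion and MS/MS annotation → loop
decomposition → assay fits.  Every tolerance and rule actually used is
recorded in the report, and a run is deterministic given the config seed.
Any stage failure halts the run with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

from . import cck, digestion, kinetics, loops, msms
from .io import PipelineConfig
from .masses import PeptideSpecies

logger = logging.getLogger("cycloms")

__all__ = ["PipelineInputs", "run_pipeline"]


@dataclass
class PipelineInputs:
    """Optional inputs; stages whose inputs are absent are skipped."""

    peaks: list[tuple[float, float]] | None = None
    candidates: list[PeptideSpecies] | None = None
    digest_target: PeptideSpecies | None = None
    spectra: dict | None = None  # title -> Spectrum, matched vs digest products
    traces: list | None = None  # KineticTrace list for an IC50 fit
    decay: tuple | None = None  # (times_h, percent_remaining)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("fingerprint")
def _fingerprint(peaks):
    count, subset = cck.ms1_fingerprint(peaks)
    return {"window": [2000.0, 4000.0], "count": count,
            "peaks": [list(p) for p in subset]}


@_stage("dereplicate")
def _dereplicate(candidates, peaks, tol):
    table = cck.dereplicate(candidates, peaks, tol)
    return table.to_dict(orient="records")


@_stage("digest")
def _digest(target, enzyme_names, max_missed):
    rules = [digestion.ENZYMES[e] for e in enzyme_names]
    products = digestion.digest(target, rules, max_missed)
    return digestion.digest_table(products).to_dict(orient="records"), products


@_stage("annotate")
def _annotate(spectra, products, tol):
    out = {}
    for title, spectrum in spectra.items():
        best = None
        for product in products:
            if abs(product.mz_h - spectrum.precursor_mz) > 0.5:
                continue
            ann = msms.annotate(spectrum, product.species, tol)
            score = ann.y_coverage + ann.b_coverage
            if best is None or score > best[0]:
                best = (score, product.sequence, ann)
        if best:
            _, seq, ann = best
            out[title] = {
                "candidate": seq,
                "y_coverage": ann.y_coverage,
                "b_coverage": ann.b_coverage,
                "n_matches": len(ann.matches),
            }
        else:
            out[title] = {"candidate": None}
    return out


@_stage("loops")
def _loops(candidates):
    out = {}
    for p in candidates:
        if p.is_cyclic() and p.sequence.count("C") == 6:
            d = loops.decompose_loops(p)
            out[p.sequence] = d.loops
    return out


@_stage("assay")
def _assay(traces):
    curve = kinetics.curve_from_traces(traces)
    fit = kinetics.fit_4pl(curve)
    return {
        "ic50": fit.ic50,
        "ic50_sd": fit.ic50_sd,
        "hill": fit.hill,
        "converged": fit.converged,
        "in_tested_range": fit.in_tested_range,
    }


@_stage("decay")
def _decay(decay):
    t, y = decay
    fit = kinetics.fit_decay(t, y)
    return {"k_per_h": fit.k, "half_life_h": fit.half_life}


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> dict:
    """Execute the requested stages; return a structured report.

    The report includes the configuration actually used and a content hash
    so identical runs can be verified to be identical.
    """
    report: dict = {
        "config": {
            "ms1_tol_da": config.ms1_tol_da,
            "ms2_tol_da": config.ms2_tol_da,
            "enzymes": list(config.enzymes),
            "seed": config.seed,
        },
        "stages": {},
    }
    if inputs.peaks is not None:
        logger.info("stage fingerprint: %d peaks", len(inputs.peaks))
        report["stages"]["fingerprint"] = _fingerprint(inputs.peaks)
    if inputs.candidates is not None and inputs.peaks is not None:
        logger.info("stage dereplicate: %d candidates, tol %.3g Da",
                    len(inputs.candidates), config.ms1_tol_da)
        report["stages"]["dereplicate"] = _dereplicate(
            inputs.candidates, inputs.peaks, config.ms1_tol_da
        )
    products = []
    if inputs.digest_target is not None:
        logger.info("stage digest: enzymes %s", config.enzymes)
        table, products = _digest(inputs.digest_target, config.enzymes, None)
        report["stages"]["digest"] = table
    if inputs.spectra is not None and products:
        logger.info("stage annotate: %d spectra, tol %.3g Da",
                    len(inputs.spectra), config.ms2_tol_da)
        report["stages"]["annotate"] = _annotate(
            inputs.spectra, products, config.ms2_tol_da
        )
    if inputs.candidates is not None:
        report["stages"]["loops"] = _loops(inputs.candidates)
    if inputs.traces is not None:
        logger.info("stage assay: %d traces", len(inputs.traces))
        report["stages"]["assay"] = _assay(inputs.traces)
    if inputs.decay is not None:
        report["stages"]["decay"] = _decay(inputs.decay)
    blob = json.dumps(report, sort_keys=True, default=str).encode()
    report["report_hash"] = hashlib.sha256(blob).hexdigest()
    return report
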