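"""End-to-end analysis: probing data to annotated structural model.

Stages (optional ones skipped when their inputs are absent):

1. normalize the SHAPE profile (2%/8%);
2. candidate models by SHAPE-directed suboptimal folding;
3. 3S model selection against independent-fragment constraints;
4. jackknife confidence of the chosen model;
5. partition function, Shannon entropy, well-defined regions;
6. DMS agreement statistic;
7. conservation: identity, structure-mapped covariation with FDR.

Every run writes a JSON manifest capturing the resolved configuration,
SHA-256 hashes of all inputs and outputs, seeds and package version; a
rerun from the manifest's configuration is byte-identical (no timestamps
enter any output).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .confidence import (confidence_entropy_table, find_well_defined_regions,
                         jackknife_confidence, shannon_entropy)
from .conservation import (average_identity, covariation_significance,
                           map_structure_to_alignment, read_stockholm)
from .dms import agreement_statistic, classify_dms
from .fold import (DEFAULT_MODEL, fold_suboptimal, partition_function,
                   structure_stats, write_ct, write_dot_bracket)
from .profiles import ReactivityProfile, read_shape_file
from .shotgun import (CROSSING_TOLERANCE, INDEPENDENCE_THRESHOLD,
                      FragmentSpec, fragment_correlation, select_model)

DEFAULT_CONFIG = {
    "normalize": True,
    "max_models": 20,
    "window": None,            # kcal/mol; None -> 20% of |MFE|
    "independence_threshold": INDEPENDENCE_THRESHOLD,
    "crossing_tolerance": CROSSING_TOLERANCE,
    "n_reps": 100,
    "drop_frac": 0.10,
    "match": "partner",
    "conf_min": 70.0,
    "ent_max": 0.2,
    "region_min_len": 40,
    "smooth_window": 51,
    "dms_high": 0.85,
    "n_perm": 1000,
    "fdr": 0.05,
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_fasta(path) -> tuple[str, str]:
    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq)


def run_pipeline(config: dict, model=DEFAULT_MODEL) -> dict:
    """Execute the full analysis described by ``config``.

    Required keys: ``sequence`` (FASTA path), ``shape`` (.shape/.map path),
    ``outdir``.  Optional: ``dms``, ``fragments`` (list of
    ``{name, start, end, profile}``), ``alignment`` (Stockholm path), and
    any of :data:`DEFAULT_CONFIG`.  Returns the result dict, including the
    manifest path.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, dict] = {}
    outputs: dict[str, str] = {}
    results: dict = {}

    def record_input(key, path):
        inputs[key] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False
        return _Ctx()

    # ---- inputs -----------------------------------------------------------
    with stage("load"):
        rna_id, sequence = _read_fasta(cfg["sequence"])
        record_input("sequence", cfg["sequence"])
        dialect = cfg.get("shape_dialect", "shape")
        shape = read_shape_file(cfg["shape"], dialect, rna_id=rna_id)
        record_input("shape", cfg["shape"])
        if len(shape) != len(sequence):
            raise ValueError(
                f"SHAPE profile length {len(shape)} != sequence length "
                f"{len(sequence)}")
        shape = ReactivityProfile(rna_id, sequence, shape.reactivities,
                                  "SHAPE", shape.offset)

    with stage("normalize"):
        if cfg["normalize"]:
            shape = shape.normalized()

    # ---- candidate models and 3S selection --------------------------------
    with stage("fold"):
        candidates = fold_suboptimal(sequence, shape, model,
                                     max_models=cfg["max_models"],
                                     window=cfg["window"])
        results["candidates"] = candidates
        cand_df = pd.DataFrame({
            "model": range(len(candidates)),
            "energy": [c.energy for c in candidates],
            "percent_paired": [structure_stats(c)["percent_paired"]
                               for c in candidates],
            "dot_bracket": [c.dot_bracket() for c in candidates],
        })
        cand_df.to_csv(outdir / "candidates.csv", index=False)
        outputs["candidates"] = "candidates.csv"

    frag_results = []
    with stage("shotgun"):
        for frag in cfg.get("fragments", []):
            spec = FragmentSpec(frag["name"], int(frag["start"]),
                                int(frag["end"]))
            fprof = read_shape_file(frag["profile"],
                                    frag.get("dialect", "shape"),
                                    rna_id=spec.name)
            record_input(f"fragment:{spec.name}", frag["profile"])
            if cfg["normalize"]:
                fprof = fprof.normalized()
            r = fragment_correlation(shape, fprof, spec)
            frag_results.append((spec, r["r"]))
        if frag_results:
            sel = select_model(candidates, frag_results,
                               threshold=cfg["independence_threshold"],
                               tolerance=cfg["crossing_tolerance"])
            sel["diagnostics"].to_csv(outdir / "shotgun.csv", index=False)
            outputs["shotgun"] = "shotgun.csv"
            chosen = sel["survivors"][0]
            results["none_consistent"] = sel["none_consistent"]
        else:
            chosen = candidates[0]
        results["chosen"] = chosen
        results["fragment_correlations"] = {s.name: r for s, r in frag_results}

    with stage("write-model"):
        write_ct(chosen, outdir / "model.ct")
        write_dot_bracket(chosen, outdir / "model.db", name=rna_id)
        outputs["model_ct"] = "model.ct"
        outputs["model_db"] = "model.db"
        results["structure_stats"] = structure_stats(chosen)

    # ---- confidence, entropy, domains -------------------------------------
    with stage("confidence"):
        conf = jackknife_confidence(sequence, shape, chosen, model,
                                    n_reps=cfg["n_reps"],
                                    drop_frac=cfg["drop_frac"],
                                    seed=cfg["seed"], match=cfg["match"])
        results["confidence"] = conf

    with stage("entropy"):
        pmat = partition_function(sequence, shape, model)
        ent = shannon_entropy(pmat)
        results["entropy"] = ent

    with stage("domains"):
        regions = find_well_defined_regions(
            conf, ent, conf_min=cfg["conf_min"], ent_max=cfg["ent_max"],
            min_len=cfg["region_min_len"], smooth_window=cfg["smooth_window"])
        results["regions"] = regions
        pd.DataFrame(regions, columns=["start", "end", "length",
                                       "mean_confidence", "mean_entropy"]
                     ).to_csv(outdir / "regions.csv", index=False)
        outputs["regions"] = "regions.csv"
        track = confidence_entropy_table(sequence, shape, conf, ent)
        track.to_csv(outdir / "track.csv", index=False)
        outputs["track"] = "track.csv"

    # ---- DMS validation ----------------------------------------------------
    if cfg.get("dms"):
        with stage("dms"):
            dms_prof = read_shape_file(cfg["dms"],
                                       cfg.get("dms_dialect", "shape"),
                                       rna_id=rna_id, reagent="DMS")
            record_input("dms", cfg["dms"])
            dms_prof = ReactivityProfile(rna_id, sequence,
                                         dms_prof.reactivities, "DMS",
                                         dms_prof.offset)
            classes = classify_dms(dms_prof)
            classes["table"].to_csv(outdir / "dms_classes.csv", index=False)
            outputs["dms_classes"] = "dms_classes.csv"
            agree = agreement_statistic(chosen, dms_prof,
                                        high=cfg["dms_high"])
            results["dms"] = {k: v for k, v in classes.items() if k != "table"}
            results["dms"].update(agree)

    # ---- conservation ------------------------------------------------------
    if cfg.get("alignment"):
        with stage("conservation"):
            aln = read_stockholm(cfg["alignment"])
            record_input("alignment", cfg["alignment"])
            col_pairs = map_structure_to_alignment(chosen, aln)
            results["average_identity"] = average_identity(aln)
            cov = covariation_significance(aln, col_pairs,
                                           n_perm=cfg["n_perm"],
                                           fdr=cfg["fdr"], seed=cfg["seed"])
            c2r = aln.col_to_ref()
            cov.insert(2, "ref_i", [c2r.get(c, 0) for c in cov["col_i"]])
            cov.insert(3, "ref_j", [c2r.get(c, 0) for c in cov["col_j"]])
            cov.to_csv(outdir / "covariation.csv", index=False)
            outputs["covariation"] = "covariation.csv"
            results["covariation"] = cov

    # ---- manifest ----------------------------------------------------------
    with stage("manifest"):
        manifest = {
            "package": "shapefold",
            "version": __version__,
            "config": {k: v for k, v in cfg.items()
                       if not isinstance(v, (dict, list)) or k == "fragments"},
            "inputs": inputs,
            "outputs": {k: {"path": v, "sha256": _sha256(outdir / v)}
                        for k, v in outputs.items()},
            "summary": {
                "rna_id": rna_id,
                "length": len(sequence),
                "n_candidates": len(results["candidates"]),
                "chosen_energy": results["chosen"].energy,
                "percent_paired": results["structure_stats"]["percent_paired"],
                "n_helices": results["structure_stats"]["n_helices"],
                "n_regions": len(results["regions"]),
                "fragment_correlations": results["fragment_correlations"],
                "average_identity": results.get("average_identity"),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = "manifest.json"
    results["manifest"] = outdir / "manifest.json"
    results["outputs"] = outputs
    return results
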