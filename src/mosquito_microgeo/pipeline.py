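"""End-to-end pipeline runner driven by a single TOML config.

Ties the stages together — simulate (or load) an OTU table, depth-filter
and rarefy, ordinate, test group structure, classify with the repeated
double-CV forest, and run the permutation validity test — writing every
numeric output as TSV/JSON into a run directory together with a manifest
(package version, config hash, input hashes, seeds) from which the run
can be reproduced exactly.

Config layout (all sections optional except one of [simulate]/[input])::

    [simulate]        # SyntheticConfig fields
    class_sizes = [10, 10, 9]
    seed = 1

    [input]           # alternative to [simulate]
    table = "table.tsv"
    metadata = "metadata.tsv"
    taxonomy = "taxonomy.tsv"

    [preprocess]
    min_reads = 7500
    rarefy_depth = "min"
    seed = 1

    [ordinate]        # NMDS + PERMANOVA on Horn distances
    n_perm = 9999

    [classify]        # RdcvConfig fields
    n_rep = 200

    [permtest]
    n_models = 400
    null_reps = 10

    [report]
    taxa = [["genus", "Wolbachia-like"]]
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecology import distance_matrix, nmds, permanova
from .permutation import build_h0, predicted_h0_mean, pvalue
from .preprocess import filter_low_depth, rarefy
from .rdcv import RdcvConfig, importance_summary, run_rdcv
from .report import taxon_report
from .synthetic import SyntheticConfig, generate_dataset
from .table import (OtuTable, read_metadata, read_table, write_metadata,
                    write_table, write_taxonomy)

log = logging.getLogger("mosquito_microgeo")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_distance(dm, path: Path) -> None:
    pd.DataFrame(dm.values, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage failures abort with the failing stage named; outputs of earlier
    stages are retained.
    """
    config_path = Path(config_path)
    cfg = tomllib.loads(config_path.read_text())
    run_dir = Path(out_dir) if out_dir else config_path.parent / "run"
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _sha256(config_path),
        "config": str(config_path),
        "inputs": {},
        "stages": [],
    }

    stage = "input"
    try:
        if "simulate" in cfg:
            sim = SyntheticConfig(**{
                k: ([tuple(m) for m in v] if k == "migrant_specs" else v)
                for k, v in cfg["simulate"].items()
            })
            table, metadata = generate_dataset(sim)
            write_table(table, run_dir / "table.tsv")
            write_taxonomy(table.taxonomy or {}, run_dir / "taxonomy.tsv")
            write_metadata(metadata, run_dir / "metadata.tsv")
            manifest["stages"].append({"stage": "simulate",
                                       "seed": sim.seed,
                                       "n_samples": table.n_samples,
                                       "n_otus": table.n_otus})
        elif "input" in cfg:
            paths = cfg["input"]
            table = read_table(paths["table"],
                               taxonomy_path=paths.get("taxonomy"))
            metadata = read_metadata(paths["metadata"])
            for key in ("table", "metadata", "taxonomy"):
                if key in paths:
                    manifest["inputs"][key] = _sha256(Path(paths[key]))
        else:
            raise ValueError("config needs a [simulate] or [input] section")
        labels = np.asarray([m.location for m in metadata
                             if m.sample_id in set(table.sample_ids)])

        if "preprocess" in cfg:
            stage = "preprocess"
            pp = cfg["preprocess"]
            table, removed = filter_low_depth(table, int(pp.get("min_reads", 7500)))
            depth = pp.get("rarefy_depth", "min")
            table = rarefy(table, depth if depth == "min" else int(depth),
                           seed=int(pp.get("seed", 0)))
            (run_dir / "removed_samples.tsv").write_text(
                "sample_id\n" + "".join(f"{s}\n" for s in removed))
            write_table(table, run_dir / "table_rarefied.tsv")
            kept = set(table.sample_ids)
            metadata = [m for m in metadata if m.sample_id in kept]
            labels = np.asarray([m.location for m in metadata])
            manifest["stages"].append({"stage": "preprocess",
                                       "removed": removed,
                                       "depth": int(table.sample_depths().min())})

        if "ordinate" in cfg:
            stage = "ordinate"
            oc = cfg["ordinate"]
            dm = distance_matrix(table)
            _write_distance(dm, run_dir / "distances.tsv")
            res = nmds(dm, seed=int(oc.get("seed", 0)))
            coords = pd.DataFrame(res.coordinates, index=list(dm.ids),
                                  columns=["NMDS1", "NMDS2"])
            coords.to_csv(run_dir / "nmds.tsv", sep="\t", index_label="sample_id")
            f, p = permanova(dm, labels, n_perm=int(oc.get("n_perm", 9999)),
                             seed=int(oc.get("seed", 0)))
            (run_dir / "permanova.json").write_text(json.dumps(
                {"pseudo_F": f, "p": p, "n_perm": int(oc.get("n_perm", 9999)),
                 "stress": res.stress}, indent=2))
            manifest["stages"].append({"stage": "ordinate", "stress": res.stress,
                                       "pseudo_F": f, "p": p})

        result = None
        if "classify" in cfg:
            stage = "classify"
            if np.unique(labels).size < 2:
                raise ValueError("classify stage needs >= 2 location labels")
            rc = RdcvConfig(**cfg["classify"])
            result = run_rdcv(table, labels, rc)
            pd.DataFrame(result.consensus_prob, index=list(result.sample_ids),
                         columns=list(result.classes)).to_csv(
                run_dir / "probabilities.tsv", sep="\t", index_label="sample_id")
            long = [
                {"sample_id": result.sample_ids[i], "class": c,
                 "repetition": r, "p": result.prob[i, j, r]}
                for i in range(len(result.sample_ids))
                for j, c in enumerate(result.classes)
                for r in range(result.prob.shape[2])
            ]
            pd.DataFrame(long).to_csv(run_dir / "prob_population.tsv",
                                      sep="\t", index=False)
            miss = [
                {"sample_id": s, "true": t, "predicted": pr}
                for s, t, pr in zip(result.sample_ids, labels, result.consensus_class)
                if t != pr
            ]
            pd.DataFrame(miss, columns=["sample_id", "true", "predicted"]).to_csv(
                run_dir / "misclassified.tsv", sep="\t", index=False)
            importance_summary(result, table.taxonomy).to_csv(
                run_dir / "importance.tsv", sep="\t", index=False)
            manifest["stages"].append({"stage": "classify", "seed": rc.seed,
                                       "n_misclassified": result.n_misclassified})

        if "permtest" in cfg:
            stage = "permtest"
            if result is None:
                raise ValueError("permtest stage requires the classify stage")
            pt = cfg["permtest"]
            rc_null = RdcvConfig(**cfg.get("classify", {}))
            h0 = build_h0(table, labels, rc_null,
                          n_models=int(pt.get("n_models", 400)),
                          seed=int(pt.get("seed", 0)),
                          null_reps=int(pt.get("null_reps", 10)))
            p = pvalue(result.n_misclassified, h0)
            pd.DataFrame({"misclassifications": list(h0.counts)}).to_csv(
                run_dir / "h0_counts.tsv", sep="\t", index=False)
            sizes = np.unique(labels, return_counts=True)[1]
            (run_dir / "permtest.json").write_text(json.dumps(
                {"mean": h0.mean, "sd": h0.sd,
                 "predicted_mean": predicted_h0_mean(sizes.tolist()),
                 "df": h0.df, "p_value": p,
                 "observed_misclassifications": result.n_misclassified},
                indent=2))
            manifest["stages"].append({"stage": "permtest", "p_value": p,
                                       "h0_mean": h0.mean})

        if "report" in cfg:
            stage = "report"
            taxa = [tuple(t) for t in cfg["report"].get("taxa", [])]
            rep = taxon_report(table, metadata, taxa)
            rep["per_sample"].to_csv(run_dir / "taxon_per_sample.tsv",
                                     sep="\t", index=False)
            rep["per_location"].to_csv(run_dir / "taxon_per_location.tsv",
                                       sep="\t", index=False)
            manifest["stages"].append({"stage": "report", "n_taxa": len(taxa)})
    except Exception as exc:
        manifest["failed_stage"] = stage
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
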