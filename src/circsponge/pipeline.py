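"""Umbrella pipeline runner: synth -> quantify -> diffexpr -> parental ->
targets -> network -> enrichstats, with a reproducibility manifest.

One YAML-able configuration drives every stage; all randomness flows through
the configured seeds, and re-running the same configuration reproduces a
byte-identical output directory (the manifest stores the configuration hash
and per-stage row counts, never timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, diffexpr, enrichstats, io, network, parental, quantify, synth, targets

log = logging.getLogger("circsponge")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "synth": {},  # SynthConfig overrides; seed defaults to the top-level seed
    "de": {"method": "pooled_binomial", "alpha": 0.05, "lfc_threshold": 1.0},
    "parental": {"mode": "coordinate", "anchor_len": 20, "require_strand": True},
    "targets": {
        "align_min": 140.0,
        "energy_max": -14.0,
        "allen_max": 4.0,
        "flank": 30,
        "allow_gu_in_seed": False,
    },
    "network": {"require_anticorrelation": False, "focus_mirna": "hub"},
    "qpcr": {"true_fold": 4.0, "noise_sd": 0.05, "n_per_group": 9},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic bundle; returns the manifest dict.

    Outputs are written under ``out_dir``: the synthetic input bundle in
    ``inputs/`` and one TSV (or GraphML/JSON) per analysis product.
    """
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "stages": {},
    }

    def record(stage: str, **counts: int) -> None:
        manifest["stages"][stage] = counts

    # --- synth ------------------------------------------------------------
    try:
        synth_kwargs = dict(cfg["synth"])
        synth_kwargs.setdefault("seed", cfg["seed"])
        scfg = synth.SynthConfig(**synth_kwargs)
        paths, truth = synth.generate_dataset(scfg, out / "inputs")
        data = synth.build(scfg)
        record("synth", n_circ=scfg.n_circ, n_genes=scfg.n_genes, n_mirna=scfg.n_mirna)
    except Exception as e:  # noqa: BLE001
        raise StageError("synth", e) from e

    # --- quantify ---------------------------------------------------------
    try:
        counts = io.read_count_matrix(paths["counts"])
        groups = io.read_group_map(paths["groups"])
        rpm_matrix = quantify.rpm(counts)
        io.write_matrix(out / "rpm.tsv", rpm_matrix, index_label="circ_id")
        record("quantify", n_circ=len(rpm_matrix), n_samples=rpm_matrix.shape[1])
    except Exception as e:  # noqa: BLE001
        raise StageError("quantify", e) from e

    # --- diffexpr ---------------------------------------------------------
    try:
        de_cfg = cfg["de"]
        group_order = scfg.group_names
        de_tables = {}
        for ref, test in zip(group_order, group_order[1:]):
            res = diffexpr.run_comparison(
                counts,
                rpm_matrix,
                groups,
                ref,
                test,
                method=de_cfg["method"],
                alpha=de_cfg["alpha"],
                lfc_threshold=de_cfg["lfc_threshold"],
            )
            name = f"{ref}_vs_{test}"
            de_tables[name] = res
            res.to_csv(out / f"de_{name}.tsv", sep="\t", lineterminator="\n")
        comp_names = list(de_tables)
        shared: list[str] = []
        if len(comp_names) >= 2:
            shared = diffexpr.shared_de(
                diffexpr.de_ids(de_tables[comp_names[0]]),
                diffexpr.de_ids(de_tables[comp_names[1]]),
            )
            pd.DataFrame({"circ_id": shared}).to_csv(
                out / "shared_de.tsv", sep="\t", index=False, lineterminator="\n"
            )
        if len(group_order) == 3 and shared:
            classifiable = []
            for cid in shared:
                try:
                    diffexpr.trend_classify(
                        [
                            float(quantify.group_mean_rpm(rpm_matrix, groups, g).loc[cid])
                            for g in group_order
                        ]
                    )
                    classifiable.append(cid)
                except ValueError:
                    continue
            trends = diffexpr.trend_table(rpm_matrix, groups, group_order, classifiable)
            trends.to_csv(out / "trends.tsv", sep="\t", lineterminator="\n")
        record(
            "diffexpr",
            **{f"n_de_{name}": len(diffexpr.de_ids(t)) for name, t in de_tables.items()},
            n_shared=len(shared),
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("diffexpr", e) from e

    # --- parental ---------------------------------------------------------
    try:
        p_cfg = cfg["parental"]
        genes = parental.genes_from_frame(io.read_gff3(paths["gff3"]))
        genome = dict(io.read_fasta(paths["genome"]))
        assignments = parental.assign_parental(
            data.circs,
            genes,
            mode=p_cfg["mode"],
            anchor_len=p_cfg["anchor_len"],
            genome=genome,
            require_strand=p_cfg["require_strand"],
        )
        aframe = parental.assignments_frame(assignments)
        aframe.to_csv(out / "parental.tsv", sep="\t", index=False, lineterminator="\n")
        annotation = io.read_annotation(paths["annotation"])
        term_table = parental.parental_term_table(assignments, annotation)
        term_table.to_csv(out / "parental_terms.tsv", sep="\t", index=False, lineterminator="\n")
        record("parental", n_assigned=int((aframe["gene_id"] != "").sum()), n_circ=len(aframe))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("parental", e) from e

    # --- targets ----------------------------------------------------------
    try:
        t_cfg = cfg["targets"]
        thresholds = targets.TargetThresholds(
            align_min=t_cfg["align_min"],
            energy_max=t_cfg["energy_max"],
            allen_max=t_cfg["allen_max"],
            flank=t_cfg["flank"],
            allow_gu_in_seed=t_cfg["allow_gu_in_seed"],
        )
        mirnas = targets.mirnas_from_fasta(io.read_fasta(paths["mirna_fasta"]))
        circ_hits = targets.predict_targets(
            io.read_fasta(paths["junction_fasta"]), mirnas, "circRNA", thresholds
        )
        mrna_hits = targets.predict_targets(
            io.read_fasta(paths["utr_fasta"]), mirnas, "mRNA", thresholds
        )
        circ_hits.to_csv(out / "circ_hits.tsv", sep="\t", index=False, lineterminator="\n")
        mrna_hits.to_csv(out / "mrna_hits.tsv", sep="\t", index=False, lineterminator="\n")
        record(
            "targets",
            n_circ_hits=int(circ_hits["pass_all"].sum()),
            n_mrna_hits=int(mrna_hits["pass_all"].sum()),
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("targets", e) from e

    # --- network ----------------------------------------------------------
    try:
        n_cfg = cfg["network"]
        first_comp = comp_names[0]
        de_circ = de_tables[first_comp].reset_index().rename(columns={"circ_id": "id"})
        de_mirna = io.read_de_table(paths["mirna_de"])
        de_mrna = io.read_de_table(paths["mrna_de"])
        g = network.build_cerna(
            circ_hits,
            mrna_hits,
            de_circ,
            de_mirna,
            de_mrna,
            require_anticorrelation=n_cfg["require_anticorrelation"],
            pathway_labels={k: tuple(v) for k, v in truth.pathway_assignment.items()},
        )
        network.write_edge_list(out / "cerna_edges.tsv", g)
        network.write_graphml(out / "cerna.graphml", g)
        axes = network.enumerate_axes(g)
        network.axes_frame(axes).to_csv(out / "axes.tsv", sep="\t", index=False, lineterminator="\n")
        focus = n_cfg["focus_mirna"]
        if focus == "hub":
            focus = truth.hub_mirna_id
        if focus and focus in g:
            sub = network.mirna_centric_subnetwork(g, focus)
            network.write_edge_list(out / "hub_subnetwork.tsv", sub)
        record("network", n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(), n_axes=len(axes))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("network", e) from e

    # --- enrichstats ------------------------------------------------------
    try:
        assigned = sorted(set(aframe.loc[aframe["gene_id"] != "", "gene_id"]))
        background = [g.gene_id for g in genes]
        enrich = enrichstats.hypergeom_enrich(assigned, annotation, background=background)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
        q_cfg = cfg["qpcr"]
        ct = synth.generate_qpcr_table(
            true_fold=q_cfg["true_fold"],
            noise_sd=q_cfg["noise_sd"],
            n_per_group=q_cfg["n_per_group"],
            seed=cfg["seed"],
        )
        qres = enrichstats.ddct(ct, "circ_target", "actin", "control", "test")
        pd.DataFrame(
            [
                {
                    "gene_id": qres.gene_id,
                    "ddct": qres.ddct,
                    "rel_expr": qres.rel_expr,
                    "p": qres.p,
                }
            ]
        ).to_csv(out / "qpcr.tsv", sep="\t", index=False, lineterminator="\n")
        luc = synth.generate_luciferase_table(seed=cfg["seed"])
        lres = enrichstats.luciferase_compare(luc)
        lres.to_csv(out / "luciferase.tsv", sep="\t", index=False, lineterminator="\n")
        record("enrichstats", n_terms=len(enrich), qpcr_rows=1, luciferase_rows=len(lres))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("enrichstats", e) from e

    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return manifest
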