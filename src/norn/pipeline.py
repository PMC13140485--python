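"""End-to-end orchestration: simulate -> segment -> proximity and
simulate -> spots -> deconv -> communication/enrichment, with a
consolidated JSON report.

A run config is a plain mapping validated against a schema (unknown keys
are rejected); every output is stamped with the config hash and seed so
identical configs give byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from norn import commun, deconv, enrich, io, proximity, segment, simulate, spots

logger = logging.getLogger(__name__)

_SIMULATE_KEYS = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
_SCHEMA: dict[str, set] = {
    "seed": set(),
    "outdir": set(),
    "conditions": set(),
    "simulate": _SIMULATE_KEYS,
    "segment": {"n_strokes_per_class", "scales", "hidden_layer_sizes", "min_object_px"},
    "proximity": {"threshold_um", "markers"},
    "spots": {"selection_gene", "threshold", "panel"},
    "deconv": {"var_quantile", "max_iter"},
    "commun": {"radius_um", "n_permutations", "min_group_size", "K", "hill_n", "alpha"},
    "enrich": {"alpha", "top"},
}


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the run config; fill defaults."""
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        if allowed and section in config:
            extra = set(config[section]) - allowed
            if extra:
                raise ValueError(f"unknown keys in section {section!r}: {sorted(extra)}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()}
    cfg.setdefault("seed", 0)
    cfg.setdefault("conditions", [{"name": "healthy", "injury": False}])
    for cond in cfg["conditions"]:
        bad = set(cond) - {"name", "injury"}
        if bad:
            raise ValueError(f"unknown keys in condition entry: {sorted(bad)}")
    cfg.setdefault("simulate", {})
    cfg.setdefault("segment", {})
    cfg.setdefault("proximity", {})
    cfg.setdefault("spots", {})
    cfg.setdefault("deconv", {})
    cfg.setdefault("commun", {})
    cfg.setdefault("enrich", {})
    return cfg


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def demo_config(seed: int = 0, injury_pair: bool = True, **simulate_overrides) -> dict:
    """A desk-scale demo run: one healthy and (optionally) one injured
    section of the same simulated animal, small enough for interactive use."""
    sim = {
        "extent": (800.0, 800.0),
        "pixel_size": 1.0,
        "n_tubules": 220,
        "n_rep_cells": 50,
        "depth": 3000.0,
        "n_background_genes": 80,
    }
    sim.update(simulate_overrides)
    conditions = [{"name": "healthy", "injury": False}]
    if injury_pair:
        conditions.append({"name": "injured", "injury": True})
    return {
        "seed": seed,
        "conditions": conditions,
        "simulate": sim,
        # K sits in the dynamic range of log1p(CP10K) expression; small
        # sections support small sender groups
        "commun": {"n_permutations": 200, "min_group_size": 3, "K": 3.0},
    }


def demo_gene_sets(signatures: pd.DataFrame) -> enrich.GeneSetCollection:
    """Gene sets derived from the simulated panel: one expression program
    per cell type (its top background genes) plus curated marker, injury
    and receptor sets. Universe = all panel genes."""
    universe = set(signatures.columns)
    sets: dict[str, set] = {
        "sglt_glucose_transport": {"Slc5a2", "Slc5a1"},
        "nephron_segment_markers": set(simulate.MARKER_GENES),
        "injury_response": set(simulate.INJURY_GENES) | {"Havcr1"},
        "lr_receptor_signaling": set(simulate.RECEPTOR_GENES),
    }
    bg = [g for g in signatures.columns if g.startswith("Bg")]
    if bg:
        for ctype in signatures.index:
            top = signatures.loc[ctype, bg].nlargest(15).index
            sets[f"{ctype}_program"] = set(top)
    return enrich.GeneSetCollection(sets=sets, universe=universe)


def _run_condition(cfg: dict, cond: dict) -> dict:
    """Simulate and analyse one condition; return report section + state."""
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs["seed"] = cfg["seed"]
    sim_kwargs["injury"] = bool(cond.get("injury", False))
    sim_cfg = simulate.SimulationConfig(**sim_kwargs)
    sample = simulate.simulate_sample(sim_cfg)
    truth = sample.truth
    markers = truth.markers

    # --- segmentation: one binary classifier per marker channel (markers
    # from sequential immunofluorescence may overlap, e.g. Sglt1 and KIM1
    # on the same injured tubule, so channels are quantified independently)
    seg_cfg = cfg["segment"]
    tissue = np.ones(markers.shape, dtype=bool)
    area_fractions: dict[str, float] = {}
    seg_iou: dict[str, float] = {}
    for name in markers.classes:
        if not markers.masks[name].any():
            continue
        strokes = simulate.sample_strokes(
            markers, sim_cfg,
            n_per_class=seg_cfg.get("n_strokes_per_class", 200),
            classes=(name,),
        )
        channel = sample.image[simulate.CHANNELS.index(name)]
        model = segment.train_classifier(
            channel,
            strokes,
            seed=cfg["seed"],
            scales=tuple(seg_cfg.get("scales", segment.DEFAULT_SCALES)),
            hidden_layer_sizes=tuple(seg_cfg.get("hidden_layer_sizes", (32,))),
            pixel_size=sim_cfg.pixel_size,
            min_object_px=seg_cfg.get("min_object_px", 5),
        )
        predicted = segment.predict_mask(model, channel)
        area_fractions[name] = segment.area_fraction(predicted.masks[name], tissue)
        seg_iou[name] = segment.iou(predicted.masks[name], markers.masks[name])

    # --- proximity on ground-truth marker masks
    prox_cfg = cfg["proximity"]
    params = proximity.ProximityParams(
        threshold_um=prox_cfg.get("threshold_um", 15.0),
        markers=tuple(prox_cfg.get("markers", ("Sglt2", "Sglt1"))),
    )
    points = truth.rep_cells[["x_um", "y_um"]].to_numpy()
    distances = proximity.nearest_distance(points, markers)
    table = proximity.classify_rep_cells(
        distances,
        params,
        meta=truth.rep_cells[["cell_id", "section_id", "animal_id"]],
    )
    table["condition"] = cond["name"]
    densities = proximity.class_density(table, params, mode="fraction")
    area_mm2 = sim_cfg.extent[0] * sim_cfg.extent[1] / 1e6
    per_area = proximity.class_density(table, params, region_area_mm2=area_mm2, mode="per_area")
    within = {
        m: proximity.within_threshold_percentage(distances, m, params)
        for m in markers.classes
        if markers.masks[m].any()
    }

    # --- spots: residuals, Epo+ selection, panel summary
    adata = sample.adata
    spot_cfg = cfg["spots"]
    rm = spots.normalize(adata)
    sel = spots.select_positive_spots(
        rm, spot_cfg.get("selection_gene", "Epo"), spot_cfg.get("threshold", 0.8)
    )
    panel = spot_cfg.get(
        "panel",
        ["Epo", "Slc5a2", "Slc5a1", "Slc12a1", "Slc12a3", "Slc14a2", "Pecam1",
         "Havcr1", "Lcn2", "Vcam1", "Tgfb1", "Acta2"],
    )
    panel_summary = (
        spots.marker_panel_summary(rm, sel, panel) if sel.n_selected else pd.DataFrame()
    )

    # --- deconvolution against the condition's reference (healthy sections
    # use a healthy reference: injured_PT is indistinguishable from PT_S2S3
    # before injury remodels its signature, so including it would split mass)
    dec_cfg = cfg["deconv"]
    reference = truth.signatures
    if not sim_cfg.injury:
        reference = reference.drop(index="injured_PT", errors="ignore")
    props = deconv.fit_proportions(
        adata,
        reference,
        var_quantile=dec_cfg.get("var_quantile", 0.5),
        max_iter=dec_cfg.get("max_iter", 500),
    )
    dominant = deconv.dominant_type(props)
    profile = deconv.composition_profile(props, sel) if sel.n_selected else pd.DataFrame()

    # --- differential expression Epo+ vs Epo- within the sample
    de = (
        spots.differential_expression(rm, adata, sel.mask, ~sel.mask)
        if sel.n_selected and (~sel.mask).sum()
        else pd.DataFrame()
    )

    # --- ORA of upregulated DEGs
    enr_cfg = cfg["enrich"]
    enrichment = pd.DataFrame()
    if len(de):
        up = de[(de["q"] < enr_cfg.get("alpha", 0.05)) & (de["delta_residual"] > 0)]
        if len(up):
            collection = demo_gene_sets(truth.signatures)
            enrichment = enrich.top_terms(
                enrich.ora(list(up.index), collection), enr_cfg.get("top", 20)
            )

    # --- communication
    comm_cfg = cfg["commun"]
    comm = None
    if sel.n_selected:
        expr = commun.normalized_expression(adata)
        groups = commun.define_senders(
            dominant,
            adata.obs[["x_um", "y_um"]].to_numpy(),
            sel.mask,
            radius_um=comm_cfg.get("radius_um", 250.0),
            min_group_size=comm_cfg.get("min_group_size", 10),
        )
        if groups:
            comm = commun.score_communication(
                expr,
                groups,
                sel.mask,
                commun.demo_lr_database(),
                B=comm_cfg.get("n_permutations", 1000),
                seed=cfg["seed"],
                condition=cond["name"],
                K=comm_cfg.get("K", 0.5),
                n=comm_cfg.get("hill_n", 1.0),
            )

    section = {
        "n_spots": int(adata.n_obs),
        "n_rep_cells": int(len(truth.rep_cells)),
        "n_epo_spots": int(sel.n_selected),
        "area_fractions": area_fractions,
        "segmentation_iou": seg_iou,
        "proximity_fractions": densities.to_dict(),
        "proximity_per_mm2": per_area.to_dict(),
        "within_threshold_pct": within,
        "epo_spot_composition_mean": (
            profile["mean"].to_dict() if len(profile) else {}
        ),
        "panel_summary_mean": (
            panel_summary["mean"].to_dict() if len(panel_summary) else {}
        ),
        "de_top20": (
            de.head(20).reset_index()[["gene", "delta_residual", "q"]].to_dict("records")
            if len(de)
            else []
        ),
        "enrichment_top": (
            enrichment[["term", "count", "gene_ratio", "q"]].to_dict("records")
            if len(enrichment)
            else []
        ),
        "communication": comm.table.to_dict("records") if comm is not None else [],
    }
    state = {
        "sample": sample,
        "residuals": rm,
        "selection": sel,
        "proximity_table": table,
        "de": de,
        "comm": comm,
        "props": props,
    }
    return section, state


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run every condition and, for a two-condition design, the paired
    comparison (area-fraction ratios, cross-condition DE of Epo+ spots,
    communication flags). Returns the report dict; writes JSON and TSV
    outputs when ``outdir`` is given."""
    cfg = validate_config(config)
    chash = config_hash(cfg)
    report = {"config_hash": chash, "seed": cfg["seed"], "conditions": {}}
    states = {}
    for cond in cfg["conditions"]:
        name = cond["name"]
        logger.info("running condition %r", name)
        try:
            section, state = _run_condition(cfg, cond)
        except Exception as err:
            raise RuntimeError(f"pipeline stage failed in condition {name!r}: {err}") from err
        report["conditions"][name] = section
        states[name] = state

    if len(cfg["conditions"]) == 2:
        (name_a, name_b) = [c["name"] for c in cfg["conditions"]]
        report["comparison"] = _compare_conditions(
            cfg, report, states[name_a], states[name_b], name_a, name_b
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        for name, state in states.items():
            io.write_table(state["proximity_table"], outdir / f"{name}_proximity.tsv", index=False)
            if len(state["de"]):
                io.write_table(state["de"], outdir / f"{name}_de.tsv")
            io.write_table(state["props"].weights, outdir / f"{name}_proportions.tsv")
    return report


def _compare_conditions(cfg, report, state_a, state_b, name_a, name_b) -> dict:
    """Paired condition contrasts, condition A taken as baseline."""
    sec_a = report["conditions"][name_a]
    sec_b = report["conditions"][name_b]
    ratios = {}
    for ch, fa in sec_a["area_fractions"].items():
        fb = sec_b["area_fractions"].get(ch)
        if fb is not None and fa > 0:
            ratios[ch] = fb / fa

    # DE between the Epo+ spots of the two conditions, on jointly
    # normalized residuals (gene panels are seed-matched across conditions)
    comparison: dict = {"area_fraction_ratio": ratios}
    ad_a = state_a["sample"].adata
    ad_b = state_b["sample"].adata
    sel_a, sel_b = state_a["selection"], state_b["selection"]
    if sel_a.n_selected and sel_b.n_selected and list(ad_a.var_names) == list(ad_b.var_names):
        Xa = ad_a.X.toarray() if hasattr(ad_a.X, "toarray") else np.asarray(ad_a.X)
        Xb = ad_b.X.toarray() if hasattr(ad_b.X, "toarray") else np.asarray(ad_b.X)
        X = np.vstack([Xa, Xb])
        joint = pd.DataFrame(X, columns=list(ad_a.var_names))
        rm = spots.pearson_residuals(joint)
        mask_b = np.concatenate([np.zeros(len(Xa), bool), sel_b.mask])
        mask_a = np.concatenate([sel_a.mask, np.zeros(len(Xb), bool)])
        de = spots.differential_expression(rm, joint, mask_b, mask_a)
        up = de[de["delta_residual"] > 0]
        ranks = {g: i for i, g in enumerate(up.index)}
        comparison["de_epo_spots_top20"] = (
            de.head(20).reset_index()[["gene", "delta_residual", "q"]].to_dict("records")
        )
        # rank among genes upregulated in condition B (the injured side)
        comparison["gene_rank_upregulated"] = {
            g: ranks.get(g, len(up)) for g in ("Havcr1", "Lcn2", "Vcam1", "Acta2", "Epo")
        }
        comp_mean_a = sec_a["epo_spot_composition_mean"]
        comp_mean_b = sec_b["epo_spot_composition_mean"]
        comparison["injured_pt_epo_weight"] = {
            name_a: comp_mean_a.get("injured_PT", 0.0),
            name_b: comp_mean_b.get("injured_PT", 0.0),
        }

    comm_a, comm_b = state_a["comm"], state_b["comm"]
    alpha = cfg["commun"].get("alpha", 0.05)
    if comm_a is not None and comm_b is not None:
        ta = comm_a.table.set_index(["sender", "interaction"])
        tb = comm_b.table.set_index(["sender", "interaction"])
        shared = ta.index.intersection(tb.index)
        if len(shared):
            flags = commun.condition_compare(
                commun.CommResult(ta.loc[shared].reset_index(), comm_a.condition),
                commun.CommResult(tb.loc[shared].reset_index(), comm_b.condition),
                alpha=alpha,
            )
            comparison["communication_flags"] = flags.to_dict("records")
        comparison["communication_significant"] = {
            name_a: comm_a.table.loc[comm_a.table["p"] < alpha, ["sender", "interaction"]].to_dict("records"),
            name_b: comm_b.table.loc[comm_b.table["p"] < alpha, ["sender", "interaction"]].to_dict("records"),
        }
    return comparison
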