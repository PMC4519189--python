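"""Workflow orchestration: membrane conditions and the full analysis run.

Four membrane conditions are studied: the native-like composition, the same
fatty acids with all head groups swapped to PC (nFA+CHOL), the native
composition without cholesterol (nFA+head), and the PC-only membrane without
cholesterol (nFA).  Removing cholesterol removes the ordered patches and
shortens the reference-interface dwell time in the synthetic dynamics;
swapping head groups to PC removes the charged lipids and therefore the
counterions.

``run_pipeline`` generates replicate synthetic trajectories per condition,
runs every analysis, clusters the dimer interfaces jointly across conditions
and writes TSV tables plus a JSON summary, fully reproducible from the
configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion as diff
from . import domains, interfaces, leaflet, protein_lipid
from .builder import BuiltSystem, default_box
from .model_io import (
    CompositionSpec,
    Frame,
    Topology,
    parse_species,
    table1_composition,
)
from .synth import (
    DEFAULT_TEMPLATES,
    DomainModel,
    InterfaceModel,
    Patch,
    SynthParams,
    generate_system,
    make_schedule,
)

__all__ = ["CONDITIONS", "derive_condition", "derive_composition", "condition_params",
           "run_pipeline"]

log = logging.getLogger("memdomain.pipeline")

CONDITIONS = ("native", "nFA+CHOL", "nFA+head", "nFA")

#: planted interface dwell means (ns) per condition; frequency of a template
#: is proportional to its dwell at uniform switching
_DWELL_MEANS = {
    "native": {"nmr": 1500.0, "alt1": 750.0, "alt2": 250.0},
    "nFA+CHOL": {"nmr": 1100.0, "alt1": 1050.0, "alt2": 380.0},
    "nFA+head": {"nmr": 450.0, "alt1": 300.0, "alt2": 1750.0},
    "nFA": {"nmr": 300.0, "alt1": 575.0, "alt2": 1625.0},
}

#: lipid diffusion speed-up in cholesterol-free membranes
_NO_CHOL_D_SCALE = 4.3


def _swap_head_to_pc(species: str) -> str:
    info = parse_species(species)
    if info.tails:
        return f"PC_{info.tails[0]}/{info.tails[1]}"
    return species


def derive_condition(system: BuiltSystem, condition: str) -> BuiltSystem:
    """Apply a condition's derivation rules to a built system."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    top = system.topology
    species = top.mol_species.copy()
    keep = np.ones(top.n_molecules, dtype=bool)
    ion_count = system.ion_count
    if condition in ("nFA+CHOL", "nFA"):
        species = np.asarray([_swap_head_to_pc(s) for s in species], dtype=object)
        ions = species == "NA"
        species[ions] = "W"  # ions are replaced by water
        ion_count = 0
    if condition in ("nFA+head", "nFA"):
        keep &= species != "CHOL"
    new_entries = [
        (s, l) for s, l, k in zip(species, top.mol_leaflet, keep) if k
    ]
    new_top = Topology.from_molecules(new_entries, n_res_protein=top.n_res_protein)
    bead_keep = keep[top.bead_mol]
    frame = Frame(
        system.frame.time, system.frame.box, system.frame.coords[bead_keep].copy()
    )
    return BuiltSystem(new_top, frame, ion_count=ion_count)


def derive_composition(spec: CompositionSpec, condition: str) -> CompositionSpec:
    """The same derivation rules on a composition recipe."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rows = list(spec.rows)
    if condition in ("nFA+CHOL", "nFA"):
        merged: dict[str, list[int]] = {}
        for s, ci, co in rows:
            t = _swap_head_to_pc(s)
            merged.setdefault(t, [0, 0])
            merged[t][0] += ci
            merged[t][1] += co
        rows = [(s, c[0], c[1]) for s, c in merged.items()]
    if condition in ("nFA+head", "nFA"):
        rows = [r for r in rows if r[0] != "CHOL"]
    out = CompositionSpec(rows, spec.water_count, spec.target_net_charge)
    out.validate()
    return out


def condition_params(
    condition: str,
    composition: CompositionSpec,
    n_frames: int,
    frame_stride: float,
    seed: int,
) -> SynthParams:
    """Planted synthetic dynamics for one condition.

    Cholesterol-containing membranes carry drifting ordered patches, slower
    lipid diffusion and a longer-lived reference interface; the dimer is
    placed outside the patches (the Ld-like environment).
    """
    has_chol = composition.count("CHOL") > 0
    in_tot, out_tot = composition.leaflet_totals()
    box = default_box(max(in_tot, out_tot, 1))
    params = SynthParams(
        n_frames=n_frames,
        frame_stride=frame_stride,
        seed=seed,
        box=tuple(box),
    )
    if not has_chol:
        params.diffusion_by_class = {
            k: (v * _NO_CHOL_D_SCALE if k not in ("PROTEIN", "W", "NA") else v)
            for k, v in params.diffusion_by_class.items()
        }
    if has_chol:
        r = 0.28 * min(box[0], box[1])
        params.domains = DomainModel(
            patches=[Patch(center=(0.3 * box[0], 0.3 * box[1]), radius=r)]
        )
        params.dimer_placement = "out-patch"
    else:
        params.dimer_placement = "free"
    rng = np.random.default_rng(seed + 77)
    schedule = make_schedule(
        params.total_ns, rng, _DWELL_MEANS[condition], start="nmr"
    )
    params.interface = InterfaceModel(schedule=schedule, templates=dict(DEFAULT_TEMPLATES))
    return params


DEFAULT_CONFIG = {
    "seed": 0,
    "replicates": 10,
    "conditions": list(CONDITIONS),
    "composition_scale": 1.0,
    "water_count": 0,
    "n_frames": 200,
    "frame_stride": 50.0,
    "analyses": ["leaflet", "profile", "interfaces", "shells", "binding", "domains", "msd"],
    "binding_n_frames": 400,
    "binding_stride": 0.5,
    "window_ns": 2000.0,
    "window_ns_no_chol": 500.0,
    "output_dir": "memdomain_out",
}


def _rep_seed(base: int, condition_index: int, rep: int) -> int:
    return int((base * 1009 + condition_index * 101 + rep * 7 + 1) % (2**31 - 1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every stage for every condition and replicate; returns the report
    dict (also written as ``summary.json``)."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    base_spec = table1_composition()
    if cfg["composition_scale"] != 1.0:
        base_spec = base_spec.scaled(cfg["composition_scale"])
    base_spec.water_count = int(cfg["water_count"])

    report: dict = {"config": _jsonable(cfg), "conditions": {}, "incomplete": []}
    all_maps: list[interfaces.ContactMap] = []
    all_run_ids: list[str] = []

    for ci, condition in enumerate(cfg["conditions"]):
        cond_report: dict = {"replicates": {}}
        composition = derive_composition(base_spec, condition)
        cond_dir = outdir / condition.replace("+", "_")
        cond_dir.mkdir(exist_ok=True)
        has_chol = composition.count("CHOL") > 0
        for rep in range(int(cfg["replicates"])):
            rep_dir = cond_dir / f"rep{rep}"
            rep_dir.mkdir(exist_ok=True)
            seed = _rep_seed(int(cfg["seed"]), ci, rep)
            params = condition_params(
                condition, composition, int(cfg["n_frames"]), float(cfg["frame_stride"]), seed
            )
            rep_report: dict = {"seed": seed}
            try:
                traj, truth = generate_system(params, composition)
            except Exception as exc:  # pragma: no cover - defensive
                log.error("generation failed for %s rep %d: %s", condition, rep, exc)
                report["incomplete"].append(f"{condition}/rep{rep}/generate")
                continue

            analyses = cfg["analyses"]
            chol_states = None
            if "leaflet" in analyses and has_chol:
                try:
                    chol_states, _ = leaflet.assign_leaflets(traj)
                    events, occupancy = leaflet.detect_flipflops(
                        chol_states, stride_ns=traj.frame_stride
                    )
                    events.to_csv(rep_dir / "flipflops.tsv", sep="\t", index=False)
                    occupancy.to_csv(rep_dir / "occupancy.tsv", sep="\t", index=False)
                    rep_report["flipflop_events"] = int(len(events))
                    rep_report["mean_outer"] = float(occupancy["n_outer"].mean())
                    rep_report["mean_inner"] = float(occupancy["n_inner"].mean())
                except Exception as exc:
                    log.error("leaflet stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/leaflet")
            if "profile" in analyses:
                try:
                    roles = ["NC3", "PO4"] + (["ROH"] if has_chol else [])
                    prof = leaflet.density_profile(traj, roles=roles)
                    pd.DataFrame(
                        {"z_nm": prof.z_centers, **prof.densities}
                    ).to_csv(rep_dir / "profile.tsv", sep="\t", index=False)
                    if has_chol:
                        rep_report["roh_distance_nm"] = leaflet.extract_distances(prof, "ROH")
                    rep_report["head_distance_nm"] = leaflet.extract_distances(prof, "NC3")
                except Exception as exc:
                    log.error("profile stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/profile")
            if "interfaces" in analyses:
                try:
                    maps = interfaces.contact_maps(traj)
                    all_maps.extend(maps)
                    all_run_ids.extend([f"{condition}/rep{rep}"] * len(maps))
                    ref = DEFAULT_TEMPLATES["nmr"]
                    trace = interfaces.nmr_trace(maps, ref)
                    trace.survival_curve().to_csv(
                        rep_dir / "nmr_survival.tsv", sep="\t", index=False
                    )
                    rep_report["nmr_present_fraction"] = float(trace.present.mean())
                    rep_report["nmr_mean_episode_ns"] = (
                        float(trace.durations.mean()) if len(trace.durations) else 0.0
                    )
                    rep_report["nmr_reformations"] = len(trace.reformations)
                except Exception as exc:
                    log.error("interface stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/interfaces")
            if "shells" in analyses:
                try:
                    enrich = protein_lipid.shell_composition(
                        traj, chol_states=chol_states
                    )
                    enrich.to_csv(rep_dir / "shells.tsv", sep="\t", index=False)
                    chol1 = enrich.query("species == 'CHOL' and shell == 1")["ratio"]
                    if len(chol1):
                        rep_report["chol_shell1_ratio"] = float(np.nanmean(chol1))
                except Exception as exc:
                    log.error("shell stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/shells")
            if "binding" in analyses:
                try:
                    bparams = replace(
                        params,
                        n_frames=int(cfg["binding_n_frames"]),
                        frame_stride=float(cfg["binding_stride"]),
                        seed=seed + 13,
                        interface=None,
                        sticky=(
                            "CHOL" if has_chol else composition.rows[0][0],
                            0.0,
                            cfg["binding_n_frames"] * cfg["binding_stride"] * 0.5,
                        ),
                    )
                    sched = make_schedule(
                        bparams.total_ns,
                        np.random.default_rng(seed + 14),
                        _DWELL_MEANS[condition],
                    )
                    bparams.interface = InterfaceModel(schedule=sched)
                    btraj, _ = generate_system(bparams, composition)
                    record = protein_lipid.max_binding_time(btraj)
                    record.per_species.to_csv(
                        rep_dir / "binding.tsv", sep="\t", index=False
                    )
                    rep_report["max_binding_ns"] = _jsonable(
                        dict(
                            zip(
                                record.per_species["species"],
                                record.per_species["max_bound_ns"],
                            )
                        )
                    )
                except Exception as exc:
                    log.error("binding stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/binding")
            if "domains" in analyses:
                try:
                    window = float(
                        cfg["window_ns"] if has_chol else cfg["window_ns_no_chol"]
                    )
                    loc = domains.protein_domain_location(
                        traj, window_ns=window, cell_size=1.0
                    )
                    rep_report["protein_ld_fraction"] = loc["ld_fraction"]
                    rep_report["protein_lo_fraction"] = loc["lo_fraction"]
                    w0 = loc["windows"][0]
                    maps = {
                        cls: domains.density_map(traj, cls, w0)
                        for cls in ("CHOL", "satmono", "poly", "protein")
                    }
                    cm = domains.classify_domains(
                        maps["CHOL"], maps["satmono"], maps["poly"], maps["protein"]
                    )
                    np.savetxt(rep_dir / "domain_map.tsv", cm.codes, fmt="%d", delimiter="\t")
                    rep_report["lo_area_fraction"] = cm.area_fraction(domains.LO_CODES)
                    rep_report["ld_area_fraction"] = cm.area_fraction(domains.LD_CODES)
                except Exception as exc:
                    log.error("domain stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/domains")
            if "msd" in analyses:
                try:
                    fits = {}
                    for gname, kw in (
                        ("lipids", {"protein": False}),
                        ("protein", {"protein": True}),
                    ):
                        res = diff.msd(traj, group=gname, **kw)
                        fits[gname] = diff.fit_diffusion(res).D_cm2_s
                    rep_report["diffusion_cm2_s"] = _jsonable(fits)
                except Exception as exc:
                    log.error("msd stage failed: %s", exc)
                    report["incomplete"].append(f"{condition}/rep{rep}/msd")
            cond_report["replicates"][f"rep{rep}"] = rep_report
        report["conditions"][condition] = cond_report

    # joint interface clustering across conditions and replicates
    if all_maps:
        try:
            clustering = interfaces.cluster_interfaces(all_maps, run_ids=all_run_ids)
            freq = clustering.frequencies
            cond_of = freq.index.str.split("/").str[0]
            cond_freq = freq.groupby(cond_of).mean()
            cond_freq.to_csv(outdir / "interface_frequencies.tsv", sep="\t")
            corr = pd.DataFrame(
                {
                    a: {
                        b: interfaces.compare_conditions(cond_freq.loc[a], cond_freq.loc[b])
                        for b in cond_freq.index
                    }
                    for a in cond_freq.index
                }
            )
            corr.to_csv(outdir / "interface_correlation.tsv", sep="\t")
            report["interface_correlation"] = _jsonable(
                {a: dict(corr[a]) for a in corr.columns}
            )
            report["frequent_clusters"] = _jsonable(clustering.frequent)
        except Exception as exc:
            log.error("joint interface clustering failed: %s", exc)
            report["incomplete"].append("interfaces/joint")

    (outdir / "summary.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report
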