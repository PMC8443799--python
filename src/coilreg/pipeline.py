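"""Stage orchestration: wire the analysis stages into reproducible workflows.

Stages are plain functions taking a parameter mapping, an output directory
and a stage seed; ``run_characterization`` executes the stages named in a
plain-text config (INI sections in order), fanning one global seed out to
per-stage seeds by stable hashing so every stage is individually
reproducible. Machine-readable outputs go to files; logs go to stderr.
Every output starts with a provenance header (stage, parameters, seed,
package version).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__ as _version
from . import assembly, binding_seq, ccgeom, rdc, register, relaxation
from . import structure_io, superpose, synthetic

logger = logging.getLogger("coilreg")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _provenance(stage: str, params: dict, seed: int) -> str:
    items = ", ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return (f"# coilreg {_version} stage={stage} seed={seed}\n"
            f"# params: {items}\n")


def _write_kv(path: Path, header: str, data: dict) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        for k, v in data.items():
            fh.write(f"{k}\t{v}\n")


# --------------------------------------------------------------------- stages

def stage_geometry(params: dict, out_dir: Path, seed: int) -> dict:
    """Coiled-coil geometry of a two-chain structure: per-residue table and
    window/heptad summary."""
    st = structure_io.read_structure(params["input"])
    ca, cb = params.get("chains", "A,B").split(",")
    fa = ccgeom.local_helix_frames(st.chain(ca))
    fb = ccgeom.local_helix_frames(st.chain(cb))
    profile = ccgeom.coiled_coil_profile(fa, fb)
    summary = ccgeom.assign_heptads(profile)
    out = {"n_positions": len(profile),
           "n_regular_heptads": summary.n_regular_heptads,
           "heptad_span": summary.heptad_span,
           "mean_radius_A": round(summary.mean_radius, 3),
           "sd_radius_A": round(summary.sd_radius, 3),
           "mean_pitch_A": (round(summary.mean_pitch, 2)
                            if math.isfinite(summary.mean_pitch) else "inf"),
           "sd_pitch_A": round(summary.sd_pitch, 2)}
    if "window" in params:
        lo, hi = (int(x) for x in params["window"].split(":"))
        w = ccgeom.summarize_window(profile, lo, hi)
        out.update({"window": f"{lo}:{hi}",
                    "window_mean_radius_A": round(w.mean_radius, 3),
                    "window_mean_pitch_A": round(w.mean_pitch, 2)})
    header = _provenance("geometry", params, seed)
    table = out_dir / "geometry_profile.tsv"
    with open(table, "w") as fh:
        fh.write(header)
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.4f")
    _write_kv(out_dir / "geometry_summary.txt", header, out)
    return out


def stage_hetnoe(params: dict, out_dir: Path, seed: int) -> dict:
    """hetNOE ratios + MC errors + flexibility classification from a peak table."""
    pairs = relaxation.read_peak_table(params["input"])
    table = relaxation.noe_ratios(pairs, n_mc=int(params.get("n_mc", 500)),
                                  seed=seed,
                                  perturb=params.get("perturb", "both"))
    table = relaxation.classify_flexible(table,
                                         cutoff=float(params.get("cutoff", 0.6)))
    out_path = out_dir / "hetnoe.tsv"
    with open(out_path, "w") as fh:
        fh.write(_provenance("hetnoe", params, seed))
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.5g")
    logger.info("flexible segments: %s", table.segments)
    return {"segments": table.segments, "n_flexible": len(table.flexible_residues())}


def stage_rdc_fit(params: dict, out_dir: Path, seed: int) -> dict:
    """Alignment-tensor fit of an RDC table against a structure."""
    st = structure_io.read_structure(params["structure"])
    chain = params.get("chain", st.chain_ids()[0])
    meas = rdc.read_rdc_table(params["rdcs"])
    vecs = structure_io.amide_vectors(st, chain_ids=[chain])
    fit = rdc.fit_tensor(vecs, meas,
                         weighted=params.get("weights", "sigma") != "unit")
    with open(out_dir / "rdc_fit.txt", "w") as fh:
        fh.write(_provenance("rdc-fit", params, seed))
        fh.write(rdc.fit_report(fit))
    return {"q_factor": fit.q, "chi2": fit.chi2, "da_hz": fit.tensor.da,
            "rhombicity": fit.tensor.rhombicity, "n_used": fit.n_used}


def stage_register_scan(params: dict, out_dir: Path, seed: int) -> dict:
    """Offset scan of measured RDCs along a template structure."""
    st = structure_io.read_structure(params["template"])
    chain = params.get("chain", st.chain_ids()[0])
    lo, hi = (int(x) for x in params["window"].split(":"))
    meas = rdc.read_rdc_table(params["rdcs"])
    hetnoe = None
    if "hetnoe" in params:
        pairs = relaxation.read_peak_table(params["hetnoe"])
        hetnoe = relaxation.noe_ratios(pairs, seed=seed)
    olo, ohi = (int(x) for x in params.get("offsets", "-10:10").split(":"))
    result = register.scan_offsets(st, chain, (lo, hi), meas, hetnoe,
                                   offsets=range(olo, ohi + 1))
    with open(out_dir / "offset_scan.tsv", "w") as fh:
        fh.write(_provenance("register-scan", params, seed))
        result.table.to_csv(fh, sep="\t", index=False, float_format="%.5g")
    out = {"best_offset": result.best_offset, "co_optimal": result.co_optimal,
           "ambiguous": result.ambiguous}
    _write_kv(out_dir / "offset_scan_summary.txt",
              _provenance("register-scan", params, seed), out)
    return out


def stage_superpose(params: dict, out_dir: Path, seed: int) -> dict:
    """Sequence-paired CA superposition with outlier rejection."""
    sa = structure_io.read_structure(params["mobile"])
    sb = structure_io.read_structure(params["reference"])
    pairing = None
    if params.get("pairing", "sequence") != "sequence":
        pairing = [tuple(int(x) for x in line.split())
                   for line in Path(params["pairing"]).read_text().split("\n")
                   if line.strip() and not line.startswith("#")]
    sup = superpose.align_with_rejection(
        sb, sa, chain_a=params.get("reference_chain"),
        chain_b=params.get("mobile_chain"), pairing=pairing,
        cycles=int(params.get("cycles", 5)),
        cutoff_sd=float(params.get("cutoff_sd", 2.0)))
    out = {"rmsd_A": round(sup.rmsd, 4), "n_pairs_final": sup.n_pairs_final,
           "n_pairs_initial": sup.n_pairs_initial,
           "n_rejected": len(sup.rejected)}
    _write_kv(out_dir / "superpose.txt", _provenance("superpose", params, seed), out)
    return out


def stage_bind_fit(params: dict, out_dir: Path, seed: int) -> dict:
    """Binding-isotherm fit of a titration table (TSV: concentration  signal)."""
    import pandas as pd
    df = pd.read_csv(params["input"], sep=r"\s+", comment="#")
    conc = df.iloc[:, 0].to_numpy()
    y = df.iloc[:, 1].to_numpy()
    mode = params.get("mode", "cosed")
    if mode == "cosed":
        fit = binding_seq.fit_kd_hyperbolic(conc, y)
    elif mode == "anisotropy":
        fit = binding_seq.fit_kd_anisotropy(conc, y,
                                            probe_conc=float(params["probe"]),
                                            model=params.get("model", "quadratic"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with open(out_dir / "binding_fit.txt", "w") as fh:
        fh.write(_provenance("bind-fit", params, seed))
        fh.write(fit.report())
    return {"kd": fit.kd, "kd_stderr": fit.kd_stderr, "model": fit.model}


def stage_simulate(params: dict, out_dir: Path, seed: int) -> dict:
    """Synthetic fixture generation (coiledcoil | rdc | relaxation | binding)."""
    what = params.get("what", "coiledcoil")
    if what == "coiledcoil":
        cp = synthetic.CrickParameters(
            r0=float(params.get("r0", synthetic.DEFAULT_R0)),
            r1=float(params.get("r1", synthetic.DEFAULT_R1)),
            pitch=float(params.get("pitch", synthetic.DEFAULT_PITCH)),
            rise=float(params.get("rise", synthetic.DEFAULT_RISE)),
            n_res=int(params.get("n_res", 70)))
        dist = synthetic.DistortionSpec(
            noise_sd=float(params.get("noise_sd", 0.0)))
        st = synthetic.generate_coiled_coil(cp, dist, seed=seed)
        path = out_dir / "coiledcoil.pdb"
        structure_io.write_pdb(st, path)
        return {"output": str(path), "n_residues": st.n_residues()}
    if what == "rdc":
        st = structure_io.read_structure(params["structure"])
        tensor = rdc.AlignmentTensor.from_parameters(
            float(params.get("da", 10.0)), float(params.get("rhombicity", 0.3)))
        meas = synthetic.simulate_rdcs(st, tensor,
                                       noise_sd=float(params.get("noise_sd", 0.0)),
                                       seed=seed,
                                       chain_ids=[params.get("chain", "A")])
        path = out_dir / "rdcs.tsv"
        rdc.write_rdc_table(meas, path)
        return {"output": str(path), "n": len(meas)}
    if what == "relaxation":
        rigid = [tuple(int(x) for x in r.split("-"))
                 for r in params.get("rigid", "115-230").split(",")]
        flexible = [tuple(int(x) for x in r.split("-"))
                    for r in params.get("flexible", "231-343").split(",")]
        pairs = synthetic.simulate_relaxation(
            rigid, flexible, noise=float(params.get("noise", 0.05)), seed=seed)
        path = out_dir / "peak_heights.tsv"
        with open(path, "w") as fh:
            fh.write("residue\theight_sat\theight_unsat\tbaseline_noise\n")
            for p in pairs:
                fh.write(f"{p.residue_number}\t{p.height_sat:.4f}\t"
                         f"{p.height_unsat:.4f}\t{p.baseline_noise:.4f}\n")
        return {"output": str(path), "n": len(pairs)}
    if what == "binding":
        conc = binding_seq.serial_dilution(float(params.get("top", 170.0)),
                                           n=int(params.get("n_points", 12)))
        df = synthetic.simulate_binding(
            params.get("model", "quadratic"), float(params.get("kd", 30.0)),
            conc, noise=float(params.get("noise", 0.03)), seed=seed,
            probe_conc=float(params["probe"]) if "probe" in params else None)
        path = out_dir / "titration.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return {"output": str(path), "n": len(df)}
    raise ValueError(f"unknown simulate target {what!r}")


def find_deposited(data_dir: str | Path, accession: str) -> Path | None:
    """Locate a user-supplied coordinate file for a PDB accession."""
    data_dir = Path(data_dir)
    for ext in (".pdb", ".cif", ".ent", ".pdb.gz", ".cif.gz"):
        for name in (accession.lower(), accession.upper()):
            p = data_dir / f"{name}{ext}"
            if p.exists():
                return p
    return None


def deposited_structure_report(data_dir: str | Path,
                               brct1_window: tuple[int, int] = (463, 565),
                               ) -> dict:
    """Printed-number analysis of the deposited entries, when supplied.

    Expects 6ZPM/6ZPJ/6ZPK and the BRCT comparison entry 3FA2 under
    ``data_dir`` (plain PDB or mmCIF; they are not redistributed with the
    package). Computes the coiled-coil geometry of the two crystal dimers
    (regular heptad counts, radius and pitch over the central six heptads,
    radius after the last regular heptad) and the cross-structure CA
    superposition RMSDs.
    """
    report: dict = {}
    p_6zpm = find_deposited(data_dir, "6zpm")
    p_6zpj = find_deposited(data_dir, "6zpj")
    p_6zpk = find_deposited(data_dir, "6zpk")
    p_3fa2 = find_deposited(data_dir, "3fa2")

    def dimer_geometry(path):
        st = structure_io.read_structure(path)
        chains = [c for c in st.chain_ids() if len(st.chain(c)) > 20][:2]
        fa = ccgeom.local_helix_frames(st.chain(chains[0]))
        fb = ccgeom.local_helix_frames(st.chain(chains[1]))
        profile = ccgeom.coiled_coil_profile(fa, fb)
        summary = ccgeom.assign_heptads(profile)
        out = {"n_regular_heptads": summary.n_regular_heptads,
               "heptad_span": summary.heptad_span}
        if summary.heptad_span is not None:
            lo, hi = summary.heptad_span
            if summary.n_regular_heptads >= 3:
                central = ccgeom.summarize_window(profile, lo + 7, hi - 7)
                out["central_radius_A"] = central.mean_radius
                out["central_radius_sd_A"] = central.sd_radius
                out["central_pitch_A"] = central.mean_pitch
                out["central_pitch_sd_A"] = central.sd_pitch
            full = ccgeom.summarize_window(profile, lo, hi)
            out["span_pitch_A"] = full.mean_pitch
            last = int(profile.residue_numbers[-1])
            if last > hi + 3:
                after = ccgeom.summarize_window(profile, hi + 1, last)
                out["after_span_radius_A"] = after.mean_radius
        return st, out

    if p_6zpm:
        st_m, report["6zpm"] = dimer_geometry(p_6zpm)
    if p_6zpj:
        st_j, report["6zpj"] = dimer_geometry(p_6zpj)
    if p_6zpm and p_6zpj:
        sup = superpose.align_with_rejection(st_m, st_j)
        report["tc_vs_lm"] = {"rmsd_A": sup.rmsd,
                              "n_ca": sup.n_pairs_final}
    if p_6zpk and p_3fa2:
        st_k = structure_io.read_structure(p_6zpk)
        st_b = structure_io.read_structure(p_3fa2)
        ck = st_k.chain_ids()[0]
        lo, hi = brct1_window
        brct1 = structure_io.Structure(chains={
            ck: [r for r in st_k.chain(ck) if lo <= r.number <= hi]})
        sup = superpose.align_with_rejection(brct1, st_b)
        report["brct1_vs_brca1"] = {"rmsd_A": sup.rmsd,
                                    "n_ca": sup.n_pairs_final}
    return report


# The paper-shaped ten BS3 crosslinks between the coiled-coil/microtubule-
# binding region and the C-terminal folded domain.
BS3_PAIRS = [(115, 499), (115, 521), (115, 543), (132, 618), (199, 521),
             (206, 521), (218, 499), (218, 510), (218, 521), (218, 618)]


def two_conformer_model(seed: int,
                        coil_range: tuple[int, int] = (115, 232),
                        linker_range: tuple[int, int] = (233, 473),
                        domain_range: tuple[int, int] = (474, 645),
                        pairs: list[tuple[int, int]] | None = None,
                        n_distal_pool: int = 10,
                        n_proximal_pool: int = 4,
                        anchor_tolerance: float = 30.0,
                        ) -> dict:
    """Build domain-proximal and domain-distal hybrid conformers and score
    the crosslink list on each.

    The chain is coiled coil + long disordered linker + compact folded
    domain. The distal conformer is the most domain-remote of a pool of
    unanchored linker draws; the proximal conformer's linker is sampled
    with its end anchored near the coiled coil's N-terminal CA (the
    extended coil library almost never returns there spontaneously).
    """
    pairs = pairs or BS3_PAIRS
    c_lo, c_hi = coil_range
    l_lo, l_hi = linker_range
    d_lo, d_hi = domain_range
    cc = synthetic.generate_coiled_coil(
        synthetic.CrickParameters(n_res=c_hi - c_lo + 1))
    coil_res = cc.chain("A")
    for i, r in enumerate(coil_res):
        r.number = c_lo + i
    coil = structure_io.Structure(chains={"A": coil_res}, source_id="coil")
    domain = synthetic.generate_compact_domain(d_hi - d_lo + 1,
                                               seed=derive_seed(seed, "domain"),
                                               start_number=d_lo)
    anchor = coil.residue("A", c_lo).coords("CA")
    prev = coil.chain("A")[-1]
    frame = tuple(prev.coords(x) for x in ("N", "CA", "C"))
    plan = assembly.SegmentPlan([
        assembly.Segment("template-threaded", c_lo, c_hi),
        assembly.Segment("random-extended", l_lo, l_hi),
        assembly.Segment("rigid-domain", d_lo, d_hi)])
    n_linker = l_hi - l_lo + 1

    def model_from(linker):
        dom = assembly.dock_onto_continuation(linker.chain("A")[-1], domain)
        model, _ = assembly.merge_models(plan, {coil_range: coil,
                                                linker_range: linker,
                                                domain_range: dom})
        return model

    ens_p = assembly.sample_linker(
        "G" * n_linker, n=n_proximal_pool, seed=derive_seed(seed, "proximal"),
        start_frame=frame, end_anchor=anchor, end_tolerance=anchor_tolerance,
        start_number=l_lo, max_retries_per_conformer=100000)
    prox_models = [model_from(c) for c in ens_p.conformers]

    def centroid_to_anchor(model):
        ca = [r.coords("CA") for r in model.chain("A")
              if d_lo <= r.number <= d_hi]
        return float(np.linalg.norm(np.mean(ca, axis=0) - anchor))

    proximal = prox_models[int(np.argmin([centroid_to_anchor(m)
                                          for m in prox_models]))]

    ens_d = assembly.sample_linker(
        "G" * n_linker, n=n_distal_pool, seed=derive_seed(seed, "distal"),
        start_frame=frame, start_number=l_lo)
    dist_models = [model_from(c) for c in ens_d.conformers]
    dist_d = [assembly.domain_proximity(m, domain_range, coil_range)
              for m in dist_models]
    distal = dist_models[int(np.argmax(dist_d))]

    res_p = assembly.crosslink_check(proximal, pairs, "BS3")
    res_d = assembly.crosslink_check(distal, pairs, "BS3")
    return {"proximal": proximal, "distal": distal,
            "fraction_proximal": res_p.fraction_compatible,
            "fraction_distal": res_d.fraction_compatible,
            "distances_proximal": res_p.distances,
            "distances_distal": res_d.distances}


def stage_assemble(params: dict, out_dir: Path, seed: int) -> dict:
    """Two-conformer hybrid model workflow; writes a two-model PDB."""
    result = two_conformer_model(seed)
    path = out_dir / "hybrid_models.pdb"
    structure_io.write_pdb([result["proximal"], result["distal"]], path)
    out = {"output": str(path),
           "fraction_compatible_proximal": result["fraction_proximal"],
           "fraction_compatible_distal": result["fraction_distal"]}
    _write_kv(out_dir / "crosslink_summary.txt",
              _provenance("assemble", params, seed), out)
    return out


STAGES: dict[str, Callable[[dict, Path, int], dict]] = {
    "simulate": stage_simulate,
    "geometry": stage_geometry,
    "hetnoe": stage_hetnoe,
    "rdc-fit": stage_rdc_fit,
    "register-scan": stage_register_scan,
    "superpose": stage_superpose,
    "bind-fit": stage_bind_fit,
    "assemble": stage_assemble,
}


def run_characterization(config_path: str | Path, out_dir: str | Path,
                         global_seed: int = 0) -> dict:
    """Execute the stages named by the config sections, in order.

    A stage failure aborts the downstream stages; results of completed
    stages are retained and the failure is flagged in the report bundle.
    Section names are stage names, optionally suffixed ':label' to repeat a
    stage. Re-running an identical config reproduces all outputs.
    """
    cfg = configparser.ConfigParser()
    cfg.optionxform = str  # keep case
    with open(config_path) as fh:
        cfg.read_file(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": global_seed, "version": _version, "stages": {}}
    for section in cfg.sections():
        stage_name = section.split(":")[0]
        if stage_name not in STAGES:
            raise ValueError(f"unknown stage {stage_name!r}")
        params = dict(cfg[section])
        for key in ("input", "structure", "template", "mobile", "reference"):
            if key in params and not Path(params[key]).exists():
                raise FileNotFoundError(
                    f"stage {section}: input {params[key]} does not exist")
        seed = derive_seed(global_seed, section)
        stage_dir = out_dir / section.replace(":", "_")
        stage_dir.mkdir(exist_ok=True)
        try:
            report["stages"][section] = STAGES[stage_name](params, stage_dir,
                                                           seed)
        except Exception as exc:   # noqa: BLE001 - abort downstream, keep partials
            logger.error("stage %s failed: %s", section, exc)
            report["stages"][section] = {"error": str(exc)}
            report["aborted_after"] = section
            break
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
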