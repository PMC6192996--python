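"""End-to-end orchestration: fit every input, compare two variants,
emit a machine-readable report.

The pipeline is configured by a flat TOML file with one table (or array
of tables) per stage; all defaults are echoed into the report so a run
is auditable from its output alone.  Stages are independent: a failure
in one is recorded under ``errors`` and the others still run.  Two runs
with identical config and seed produce identical report.json content.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .contacts import (align_rmsd, normalized_bfactor, read_structure,
                       residue_network, survey_salt_bridges)
from .kinetics import fit_michaelis_menten, read_kinetics_csv
from .seqtools import column_conservation, read_alignment_fasta
from .thermal import (fit_melting_curve,
                      read_melting_curve, _default_init)

__all__ = ["load_config", "run_compare_variants"]


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "enzstab_out")
    cfg["_config_dir"] = str(Path(path).resolve().parent)
    return cfg


def _resolve(cfg: dict, p: str) -> Path:
    path = Path(p)
    if not path.is_absolute() and "_config_dir" in cfg:
        path = Path(cfg["_config_dir"]) / path
    return path


def _fit_one_melt(cfg: dict, entry: dict) -> dict:
    curve = read_melting_curve(_resolve(cfg, entry["path"]),
                               temperature_unit=entry.get("temperature_unit", "K"),
                               label=entry.get("label"))
    fixed = ["dCp", "slope_folded", "slope_unfolded"]
    init = _default_init(curve)
    if "fix_baselines" in entry:
        ef, eu = entry["fix_baselines"]
        init.eps_folded, init.eps_unfolded = float(ef), float(eu)
        fixed += ["eps_folded", "eps_unfolded"]
    if entry.get("fit_dcp"):
        fixed.remove("dCp")
    if entry.get("fit_slopes"):
        fixed = [f for f in fixed if not f.startswith("slope")]
    fit = fit_melting_curve(curve, init=init, fixed=fixed)
    return fit.to_dict()


def _kinetics_row(cfg: dict, entry: dict) -> dict:
    data = read_kinetics_csv(_resolve(cfg, entry["path"]))
    fit = fit_michaelis_menten(data)
    row = {"label": entry.get("label", data.label),
           "substrate": data.substrate,
           "temperature_c": data.temperature_c,
           "enzyme_um": data.enzyme_um}
    row.update(fit.to_dict())
    return row


def _parse_residue_selector(sel: str) -> tuple[str, int]:
    chain, _, num = sel.partition(":")
    return chain, int(num)


def _structure_report(cfg: dict, entry: dict) -> dict:
    s = read_structure(_resolve(cfg, entry["path"]))
    rep: dict = {"label": entry.get("label", s.id), "chains": s.chains()}
    if "residue" in entry:
        chain, num = _parse_residue_selector(entry["residue"])
        edges = residue_network(s, chain, num,
                                cutoff=float(entry.get("cutoff", 3.5)),
                                his_charged=bool(entry.get("his_charged", False)))
        rep["network"] = [asdict(e) for e in edges]
        rep["has_salt_bridge"] = any(e.kind == "salt_bridge" for e in edges)
    if "bfactor_residues" in entry:
        targets = [(int(num), str(name)) for num, name in entry["bfactor_residues"]]
        b = normalized_bfactor(s, targets,
                               side_chain_only=bool(entry.get("side_chain_only", True)))
        rep["bfactor"] = asdict(b)
    return rep


def run_compare_variants(config: dict | str | Path) -> dict:
    """Run every configured stage and write report.json / report.txt.

    Returns the report dict.  Per-stage errors are caught and recorded;
    independent stages still complete.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(cfg.get("output_dir", "enzstab_out"))
    if not outdir.is_absolute() and "_config_dir" in cfg:
        outdir = Path(cfg["_config_dir"]) / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    public_cfg = {k: v for k, v in cfg.items() if not k.startswith("_")}
    report: dict = {
        "provenance": {
            "package": "enzstab",
            "version": __version__,
            "seed": cfg.get("seed", 0),
            "config_sha256": hashlib.sha256(
                json.dumps(public_cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "config": public_cfg,
        },
        "errors": {},
    }

    def _stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            print(f"[enzstab] stage {name} failed: {exc}", file=sys.stderr)

    if cfg.get("melts"):
        def _melts():
            fits = {e.get("label", f"melt{i}"): _fit_one_melt(cfg, e)
                    for i, e in enumerate(cfg["melts"])}
            labels = list(fits)
            out = {"fits": fits}
            if len(labels) >= 2:
                a, b = fits[labels[0]], fits[labels[1]]
                if a["converged"] and b["converged"]:
                    out["delta_tm"] = b["params"]["tm"] - a["params"]["tm"]
            return out
        _stage("melts", _melts)

    if cfg.get("kinetics"):
        def _kin():
            rows = [_kinetics_row(cfg, e) for e in cfg["kinetics"]]
            pd.DataFrame(rows).to_csv(outdir / "kinetics_fits.csv", index=False)
            return rows
        _stage("kinetics", _kin)

    if cfg.get("structures"):
        def _structs():
            return [_structure_report(cfg, e) for e in cfg["structures"]]
        _stage("structures", _structs)

    if cfg.get("align"):
        def _align():
            a = read_structure(_resolve(cfg, cfg["align"]["a"]))
            b = read_structure(_resolve(cfg, cfg["align"]["b"]))
            r = align_rmsd(a, b,
                           selection=cfg["align"].get("selection", "CA"),
                           cycles=int(cfg["align"].get("cycles", 5)),
                           reject_sigma=float(cfg["align"].get("reject_sigma", 2.0)))
            return {"rmsd": r.rmsd, "n_atoms_used": r.n_atoms_used,
                    "n_atoms_start": r.n_atoms_start, "cycles_run": r.cycles_run}
        _stage("align", _align)

    if cfg.get("survey"):
        def _survey():
            manifest = pd.read_csv(_resolve(cfg, cfg["survey"]["manifest"]), sep="\t")
            entries = []
            for _, row in manifest.iterrows():
                s = read_structure(_resolve(cfg, row["path"]))
                entries.append((row["label"], s, row["chain"],
                                int(row["pos_a"]), int(row["pos_b"])))
            table = survey_salt_bridges(entries,
                                        cutoff=float(cfg["survey"].get("cutoff", 3.5)))
            table.to_csv(outdir / "salt_bridge_survey.csv", index=False)
            return table.to_dict(orient="records")
        _stage("survey", _survey)

    if cfg.get("conservation"):
        def _cons():
            c = cfg["conservation"]
            aln = read_alignment_fasta(_resolve(cfg, c["alignment"]),
                                       reference=c.get("reference"))
            rep = column_conservation(aln, int(c["position"]))
            return asdict(rep)
        _stage("conservation", _cons)

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=str) + "\n")
    (outdir / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: dict) -> str:
    lines = [f"enzstab {report['provenance']['version']} report",
             f"config sha256: {report['provenance']['config_sha256']}",
             f"seed: {report['provenance']['seed']}", ""]
    melts = report.get("melts", {})
    for label, fit in melts.get("fits", {}).items():
        p = fit["params"]
        ci = fit["ci95"].get("tm")
        ci_txt = f" (95% CI {ci[0]:.1f}-{ci[1]:.1f})" if ci else ""
        lines.append(f"melt {label}: Tm = {p['tm']:.2f} K{ci_txt}, "
                     f"dH = {p['dH']:.0f} kJ/mol, converged={fit['converged']}")
    if "delta_tm" in melts:
        lines.append(f"delta Tm (second - first) = {melts['delta_tm']:.2f} K")
    for row in report.get("kinetics", []):
        lines.append(f"kinetics {row['label']}: kcat = {row['kcat']:.3g} 1/s, "
                     f"Km = {row['km']:.3g} uM, kcat/Km = {row['efficiency']:.3g} 1/s/mM")
    for srep in report.get("structures", []):
        if "has_salt_bridge" in srep:
            lines.append(f"structure {srep['label']}: "
                         f"{len(srep.get('network', []))} polar contact(s), "
                         f"salt bridge: {srep['has_salt_bridge']}")
        if "bfactor" in srep:
            lines.append(f"structure {srep['label']}: combined normalized "
                         f"B-factor = {srep['bfactor']['cross_chain_combined']:.3f}")
    if "align" in report:
        a = report["align"]
        lines.append(f"alignment RMSD = {a['rmsd']:.3f} A over "
                     f"{a['n_atoms_used']} atoms")
    if "conservation" in report:
        c = report["conservation"]
        lines.append(f"conservation at reference position "
                     f"{c['reference_position']}: {c['frequencies']}, "
                     f"invariant={c['is_invariant']}")
    for stage, err in report.get("errors", {}).items():
        lines.append(f"ERROR in stage {stage}: {err}")
    return "\n".join(lines) + "\n"
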