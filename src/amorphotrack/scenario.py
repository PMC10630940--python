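"""End-to-end scenario runner: generate -> deconvolve -> fit -> map -> report.

A :class:`RunConfig` (YAML-friendly dict, schema-validated, unknown keys
rejected) drives the full chain for one preset:

  dielectric: spectra series -> (deconvolution for confined presets) ->
  per-temperature HN fits -> tau map -> VFT / Tg -> crossover test ->
  master-curve KWW fit -> coupling-model JG check;
  thermal: multi-rate thermograms -> event extraction -> double-event
  report -> Kissinger regression(s);
  dissolution: profile -> release fit -> classification.

Outputs (JSON report, markdown summary, resolved config, CSV data) are
deterministic for a fixed config: one seeded generator feeds every stage and
report floats are serialized with repr precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from ._constants import TAU_REF_TG
from .dissolution import fit_release, summary_metrics, write_profile
from .fitting import cm_jg_test, fit_hn, fit_kww, tau_max_from_hn
from .relaxmap import TauMap, detect_crossover, fit_vft, tg_from_vft
from .spectra import deconvolve_composite, normalize_peak, write_spectra
from .synthetic import (
    PRESET_NAMES,
    default_freq_grid,
    gen_dissolution,
    gen_dsc,
    gen_spectra_series,
    law_tg,
    preset,
)
from .thermal import detect_double_events, extract_events, kissinger_multi, write_dsc

__all__ = ["RunConfig", "run_scenario"]

_SCHEMA = {
    "scenario": str,
    "seed": int,
    "outdir": str,
    "temps": {"start": float, "stop": float, "step": float},
    "freq": {"fmin": float, "fmax": float, "per_decade": int},
    "rates": list,
    "noise": {"bds_rel": float, "dsc_abs": float, "dissolution_rel": float},
    "dissolution_times": list,
    "protocol": str,
    "write_data": bool,
}

_DEFAULTS = {
    "scenario": "bulk_apz",
    "seed": 0,
    "outdir": "scenario_out",
    "temps": {"start": 309.0, "stop": 339.0, "step": 1.0},
    "freq": {"fmin": 1e-3, "fmax": 1e6, "per_decade": 10},
    "rates": [2.5, 5.0, 7.5, 10.0, 20.0],
    "noise": {"bds_rel": 0.01, "dsc_abs": 0.01, "dissolution_rel": 0.03},
    "dissolution_times": [float(t) for t in range(10, 181, 10)],
    "protocol": "slow_heat",
    "write_data": False,
}


def _validate(node, schema, defaults, path=""):
    if not isinstance(node, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    out = {}
    for key, val in node.items():
        if key not in schema:
            raise ValueError(f"unknown config key {path + key!r}")
        want = schema[key]
        if isinstance(want, dict):
            out[key] = _validate(val, want, defaults[key], path + key + ".")
        elif want is float:
            out[key] = float(val)
        elif want is int:
            out[key] = int(val)
        elif want is bool:
            if not isinstance(val, bool):
                raise ValueError(f"config key {path + key!r} must be a boolean")
            out[key] = val
        elif want is list:
            out[key] = [float(v) for v in val]
        else:
            out[key] = str(val)
    for key, dv in defaults.items():
        if key not in out:
            out[key] = json.loads(json.dumps(dv)) if isinstance(dv, dict) else dv
    return out


@dataclass
class RunConfig:
    """Validated scenario configuration (see module docstring)."""

    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = _validate(d or {}, _SCHEMA, _DEFAULTS)
        if cfg["scenario"] not in PRESET_NAMES:
            raise ValueError(
                f"unknown scenario {cfg['scenario']!r}; choose from {PRESET_NAMES}"
            )
        return cls(raw=cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.raw[key]


def _round_floats(obj, ndig=10):
    if isinstance(obj, float):
        return round(obj, ndig) if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _dielectric_chain(pst, cfg, rng, outdir, report):
    t = cfg["temps"]
    fr = cfg["freq"]
    grid = default_freq_grid(fr["fmin"], fr["fmax"], fr["per_decade"])
    series = gen_spectra_series(
        pst, t["start"], t["stop"], t["step"], cfg["protocol"],
        seed=int(rng.integers(2 ** 31)), freq_grid=grid,
        noise_rel=cfg["noise"]["bds_rel"],
    )
    if cfg["write_data"]:
        write_spectra(series, outdir / "spectra.csv")
    geom = pst.matrix.geometry() if pst.matrix is not None else None

    pairs = []
    spectra_api = []
    for s in series:
        api = deconvolve_composite(s, geom) if geom is not None else s
        spectra_api.append(api)
        # window around the fastest (structural) peak, away from any slow
        # interfacial/MWS contribution; subtract a crude dc-conductivity
        # estimate first so its 1/f wing cannot masquerade as the peak
        y = api.eps_imag
        if pst.conductivity is not None:
            from ._constants import EPS0

            sig0 = y[0] * EPS0 * 2.0 * np.pi * api.freq[0]
            y = y - sig0 / (EPS0 * 2.0 * np.pi * api.freq)
        mask = api.freq >= 0.05
        fpk = api.freq[mask][int(np.argmax(y[mask]))]
        window = (fpk / 10 ** 1.5, fpk * 10 ** 2.5)
        use_cond = pst.conductivity is not None
        try:
            fit = fit_hn(api, 1, use_conductivity=use_cond, window=window, seed=7)
        except (ValueError, RuntimeError):
            continue
        pairs.append((s.T, fit))

    if len(pairs) < 5:
        raise RuntimeError("dielectric stage: too few successful HN fits")
    tau_map = TauMap(
        "alpha",
        np.array([T for T, _ in pairs]),
        np.array([tau_max_from_hn(f.processes[0]) for _, f in pairs]),
    )
    cross = detect_crossover(tau_map)
    vft = fit_vft(tau_map, min_decades=0.0)
    if cross.detected and cross.high_t_law is not None:
        tg_bds = cross.high_t_law.tg if math.isfinite(cross.high_t_law.tg) else vft.tg
    else:
        tg_bds = vft.tg

    # master curve: spectrum whose structural peak is nearest 10 Hz, with the
    # fitted dc-conductivity wing removed before normalization
    k_best = min(
        range(len(pairs)),
        key=lambda k: abs(
            math.log10(2.0 * math.pi * tau_max_from_hn(pairs[k][1].processes[0]) * 10.0)
        ),
    )
    best = spectra_api[[s.T for s in spectra_api].index(pairs[k_best][0])]
    bfit = pairs[k_best][1]
    if bfit.sigma_dc:
        from ._constants import EPS0

        cond = bfit.sigma_dc / (EPS0 * 2.0 * np.pi * best.freq)
        best = replace(best, eps_imag=np.clip(best.eps_imag - cond, 1e-12, None))
    fpk = 1.0 / (2.0 * math.pi * tau_max_from_hn(bfit.processes[0]))
    peak = normalize_peak(best, (fpk / 10 ** 1.5, fpk * 10 ** 2.5))
    kww = fit_kww(peak)
    tau_alpha_tg = TAU_REF_TG
    cm = cm_jg_test(tau_alpha_tg, kww.beta_kww)

    # for a planted crossover law the comparable Tg is the one of its VFT
    # branch (the analysis extrapolates the high-T law to tau = 100 s)
    law = pst.processes[0].law
    law = getattr(law, "vft", law)
    planted = {"tg_alpha_planted": law_tg(law)}
    report["dielectric"] = {
        "n_spectra": len(series),
        "n_fits": len(pairs),
        "tau_map_T": [float(x) for x in tau_map.index],
        "tau_map_log10_tau": [float(x) for x in np.log10(tau_map.tau)],
        "vft": {"tau_vft": vft.tau_vft, "d_t": vft.d_t, "t0": vft.t0, "tg": vft.tg},
        "crossover": {
            "detected": bool(cross.detected),
            "t_cross": cross.t_cross if cross.detected else None,
            "f_ratio": cross.f_ratio,
            "ea_low_kj": cross.low_t_law.ea_kj if cross.detected else None,
        },
        "tg_bds": tg_bds,
        "kww": {"beta": kww.beta_kww, "resid": kww.resid_norm, "poor_fit": kww.poor_fit},
        "cm": {"n": cm.n, "log10_tau0": math.log10(cm.tau0), "verdict": cm.verdict},
        **planted,
    }


def _thermal_chain(pst, cfg, rng, outdir, report):
    events_by_rate = {}
    groups: dict = {}
    for rate in cfg["rates"]:
        tg = gen_dsc(
            pst.dsc, rate, noise_abs=cfg["noise"]["dsc_abs"],
            seed=int(rng.integers(2 ** 31)), sample=pst.name,
        )
        if cfg["write_data"]:
            write_dsc(tg, outdir / f"dsc_{rate:g}Kmin.csv")
        ev = extract_events(tg)
        events_by_rate[rate] = ev
        tcs = ev.tc_temps
        if len(tcs) >= 2:
            groups.setdefault("first", []).append((rate, tcs[0]))
            groups.setdefault("second", []).append((rate, tcs[-1]))
        elif len(tcs) == 1:
            groups.setdefault("merged", []).append((rate, tcs[0]))
    double = detect_double_events(events_by_rate)
    kiss = kissinger_multi(groups)
    report["thermal"] = {
        "events": {
            f"{rate:g}": {
                "tg": ev.tg_temps, "tc": ev.tc_temps, "tm": ev.tm_temps,
                "delta_cp": [g.delta_cp for g in ev.tg_list],
            }
            for rate, ev in events_by_rate.items()
        },
        "double_crystallization": {
            "counts": {f"{k:g}": v for k, v in double.counts.items()},
            "merge_threshold": double.merge_threshold,
            "always_double": double.always_double,
        },
        "kissinger": {
            label: {
                "e_cr_kj": r.e_cr_kj, "c_k": r.c_k,
                "stderr_e_cr_kj": r.stderr_e_cr_kj, "r_squared": r.r_squared,
            }
            for label, r in kiss.items()
        },
        "planted_ea_cr_kj": list(pst.dsc.ea_cr_kj),
        "planted_tg": list(pst.dsc.tg_list),
        "planted_tm": list(pst.dsc.tm_list),
    }


def _dissolution_chain(pst, cfg, rng, outdir, report):
    prof = gen_dissolution(
        pst.dissolution_kind if pst.dissolution_kind != "prolonged" else "prolonged",
        pst.dissolution_params,
        times=np.array(cfg["dissolution_times"]),
        noise_rel=cfg["noise"]["dissolution_rel"],
        seed=int(rng.integers(2 ** 31)),
        sample=pst.name,
    )
    if cfg["write_data"]:
        write_profile(prof, outdir / "dissolution.csv")
    fit = fit_release(prof)
    met = summary_metrics(prof)
    report["dissolution"] = {
        "label": fit.label,
        "model": fit.model,
        "params": fit.params,
        "metrics": asdict(met),
        "planted_kind": pst.dissolution_kind,
    }


def run_scenario(config: RunConfig | dict, outdir=None) -> dict:
    """Run the full analysis chain for one preset; write report bundle.

    Returns the report dict.  Any stage failure raises with the stage name;
    partial outputs written so far are left in place.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config.raw
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    pst = preset(cfg["scenario"])
    rng = np.random.default_rng(cfg["seed"])
    report: dict = {"scenario": cfg["scenario"], "seed": cfg["seed"]}
    for name, stage in (
        ("dielectric", _dielectric_chain),
        ("thermal", _thermal_chain),
        ("dissolution", _dissolution_chain),
    ):
        try:
            stage(pst, cfg, rng, out, report)
        except Exception as exc:
            _write_report(out, report)
            raise RuntimeError(f"scenario stage {name!r} failed: {exc}") from exc
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    clean = _round_floats(report)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write(_markdown(clean))


def _markdown(r: dict) -> str:
    lines = [f"# Scenario report: {r.get('scenario')}", ""]
    d = r.get("dielectric")
    if d:
        lines += [
            "## Dielectric",
            f"- Tg (BDS, tau = 100 s): {d['tg_bds']:.2f} K"
            f" (planted {d['tg_alpha_planted']:.2f} K)",
            f"- VFT: tau_vft = {d['vft']['tau_vft']:.3e} s, D_T = {d['vft']['d_t']:.3f},"
            f" T0 = {d['vft']['t0']:.2f} K",
            f"- crossover detected: {d['crossover']['detected']}"
            + (
                f" at {d['crossover']['t_cross']:.1f} K"
                if d["crossover"]["detected"]
                else ""
            ),
            f"- beta_KWW = {d['kww']['beta']:.3f} (poor fit: {d['kww']['poor_fit']})",
            f"- CM: n = {d['cm']['n']:.3f}, log10 tau0 = {d['cm']['log10_tau0']:.2f},"
            f" verdict {d['cm']['verdict']}",
            "",
        ]
    t = r.get("thermal")
    if t:
        lines += ["## Thermal"]
        for rate, ev in sorted(t["events"].items(), key=lambda kv: float(kv[0])):
            lines.append(
                f"- {rate} K/min: Tg {[round(x, 1) for x in ev['tg']]},"
                f" Tc {[round(x, 1) for x in ev['tc']]},"
                f" Tm {[round(x, 1) for x in ev['tm']]}"
            )
        lines.append(
            f"- double crystallization merge threshold: {t['double_crystallization']['merge_threshold']}"
        )
        for label, k in t["kissinger"].items():
            lines.append(
                f"- Kissinger[{label}]: E_cr = {k['e_cr_kj']:.1f} kJ/mol (r2 = {k['r_squared']:.4f})"
            )
        lines.append(f"- planted E_cr: {t['planted_ea_cr_kj']} kJ/mol")
        lines.append("")
    di = r.get("dissolution")
    if di:
        lines += [
            "## Dissolution",
            f"- class: {di['label']} (model {di['model']},"
            f" planted kind {di['planted_kind']})",
            f"- Cmax = {di['metrics']['c_max']:.3f} mg/mL at"
            f" {di['metrics']['t_c_max']:.0f} min; AUC = {di['metrics']['auc']:.2f}",
            "",
        ]
    return "\n".join(lines)
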