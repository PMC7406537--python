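"""End-to-end two-stage driver and plain-text definition files.

``RunConfig`` captures everything a run needs — data location, stage-1 and
stage-2 model definitions, quadrature and convergence options, seed and
imputation count — and round-trips losslessly through a keyword-based
definition (.def) file, one ``key = value`` pair per line.
``run_two_stage`` executes the full workflow and writes the report
artifacts (stage-1 report with descriptives and all three submodels, ebvar
file, stage-2 pooled report, optional draws export).
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from .data import (aggregate_to_subject_level, decompose_within_between,
                   read_longitudinal_csv)
from .errors import MixLSError, SpecificationError
from .mels import MELS
from .memls import MEMLS
from .plausible import draw_plausible_values
from .report import (format_descriptives, format_stage1_chain,
                     format_stage2_results)
from .stage2 import Stage2Spec, fit_stage2

__all__ = ["RunConfig", "run_two_stage", "save_def", "load_def"]

_LIST_FIELDS = {"mean", "bs_var", "ws_var", "random_slopes",
                "decompose", "stage2_regressors", "interact_location",
                "interact_slope", "interact_scale", "three_way"}
_BOOL_FIELDS = {"random_scale", "adaptive", "suppress_interactions",
                "save_draws", "location_by_scale"}


@dataclass
class RunConfig:
    data: str = ""
    id_column: str | None = None        # default: first column
    outcome: str | None = None          # default: second column
    mean: list = field(default_factory=list)
    bs_var: list = field(default_factory=list)
    ws_var: list = field(default_factory=list)
    random_slopes: list = field(default_factory=list)
    ncov: int = 1
    random_scale: bool = True
    missing_code: float | None = None
    decompose: list = field(default_factory=list)
    quad_points: int | None = None
    adaptive: bool = True
    tol: float = 1e-5
    max_iter: int = 100
    ridge: float = 0.0
    stage2_outcome: str | None = None
    stage2_type: str = "continuous"
    stage2_regressors: list = field(default_factory=list)
    interact_location: list = field(default_factory=list)
    interact_slope: list = field(default_factory=list)
    interact_scale: list = field(default_factory=list)
    three_way: list = field(default_factory=list)
    location_by_scale: bool = True
    suppress_interactions: bool = False
    seed: int = 1
    n_imputations: int = 500
    save_draws: bool = False
    out_prefix: str = "mixls_run"

    def stage2_spec(self):
        plan = {}
        for name in self.stage2_regressors:
            flags = set()
            if name in self.interact_location:
                flags.add("location")
            if name in self.interact_slope:
                flags.add("slope")
            if name in self.interact_scale:
                flags.add("scale")
            if name in self.three_way:
                flags.add("three_way")
            if flags:
                plan[name] = flags
        return Stage2Spec(
            outcome=self.stage2_outcome, outcome_type=self.stage2_type,
            regressors=list(self.stage2_regressors), interactions=plan,
            include_location_by_scale=self.location_by_scale,
            suppress_all_interactions=self.suppress_interactions)

    def used_variables(self):
        used = []
        for name in ([self.outcome] + self.mean + self.bs_var + self.ws_var
                     + self.random_slopes + self.decompose
                     + ([self.stage2_outcome] if self.stage2_outcome else [])
                     + self.stage2_regressors):
            base = name
            for suf in ("_BS", "_WS"):
                if name and name.endswith(suf):
                    base = name[:-len(suf)]
            if base and base not in used:
                used.append(base)
        return used


def save_def(config, path):
    """Serialize a RunConfig to a keyword definition file."""
    lines = ["# mixls definition file"]
    for f in dataclasses.fields(RunConfig):
        v = getattr(config, f.name)
        if f.name in _LIST_FIELDS:
            v = ",".join(v)
        elif v is None:
            v = ""
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_def(path):
    """Parse a definition file back into a RunConfig (lossless)."""
    cfg = RunConfig()
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise SpecificationError(f"unknown definition key {key!r}")
        if key in _LIST_FIELDS:
            setattr(cfg, key, [s for s in val.split(",") if s])
        elif key in _BOOL_FIELDS:
            setattr(cfg, key, val == "True")
        elif val == "":
            # blank means None for optional fields, "" for plain strings
            setattr(cfg, key,
                    None if "None" in str(fields[key].type) else "")
        else:
            ftype = fields[key].type
            if "int" in str(ftype):
                setattr(cfg, key, int(val))
            elif "float" in str(ftype):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
    return cfg


def _build_stage1(config, data):
    common = dict(quad_points=config.quad_points, adaptive=config.adaptive,
                  tol=config.tol, max_iter=config.max_iter,
                  ridge=config.ridge)
    if config.random_slopes:
        if config.ncov not in (0, 1):
            raise SpecificationError(
                "ncov must be 0 or 1 when random slopes are present")
        return MEMLS(data, config.outcome, mean=config.mean,
                     random_slopes=config.random_slopes,
                     ws_var=config.ws_var, ncov=config.ncov,
                     random_scale=config.random_scale, **common)
    qp = common.pop("quad_points")
    return MELS(data, config.outcome, mean=config.mean,
                bs_var=config.bs_var, ws_var=config.ws_var,
                ncov=config.ncov, random_scale=config.random_scale,
                quad_points=11 if qp is None else qp, **common)


def run_two_stage(config, verbose=False):
    """Execute the full two-stage workflow described by ``config``.

    Returns a dict with the fitted objects and the paths of the written
    artifacts.  On failure a log file ``<prefix>.log`` is persisted with
    the traceback and the error is re-raised.
    """
    prefix = Path(config.out_prefix)
    try:
        return _run(config, prefix, verbose)
    except Exception as exc:
        prefix.parent.mkdir(parents=True, exist_ok=True)
        log = prefix.with_suffix(".log")
        log.write_text(
            f"two-stage run failed: {exc}\n\n{traceback.format_exc()}")
        raise


def _run(config, prefix, verbose):
    data, drop_report = read_longitudinal_csv(
        config.data, id_column=config.id_column,
        missing_code=config.missing_code,
        used_variables=config.used_variables() or None)
    if config.id_column is None:
        config.id_column = data.id_col
    if config.outcome is None:
        cols = [c for c in data.frame.columns if c != data.id_col]
        config.outcome = cols[0]
    for var in config.decompose:
        data = decompose_within_between(data, var)
    model = _build_stage1(config, data)
    res1 = model.fit()
    prefix.parent.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    desc_vars = [config.outcome] + [
        v for v in (config.mean + config.ws_var + config.bs_var
                    + config.random_slopes) if v in data.frame.columns]
    stage1_txt = (
        format_descriptives(data.frame, desc_vars, "occasion level")
        + f"\nRows dropped by listwise deletion: "
        f"{drop_report['rows_dropped']}"
        f" (subjects fully removed: {drop_report['subjects_dropped']})\n\n"
        + format_stage1_chain(res1))
    p1 = prefix.parent / (prefix.name + "_stage1.txt")
    p1.write_text(stage1_txt)
    artifacts["stage1_report"] = p1
    eb = res1.empirical_bayes()
    pe = prefix.parent / (prefix.name + "_ebvar.csv")
    eb.save(pe)
    artifacts["ebvar"] = pe
    pd_ = prefix.parent / (prefix.name + ".def")
    save_def(config, pd_)
    artifacts["definition"] = pd_
    result = {"stage1": res1, "eb": eb, "artifacts": artifacts, "status": 0}
    if config.stage2_outcome is None:
        if verbose:
            print("no stage-2 outcome: stage 2 bypassed")
        return result
    draws = draw_plausible_values(eb, n_imputations=config.n_imputations,
                                  seed=config.seed)
    if config.save_draws:
        pdr = prefix.parent / (prefix.name + "_draws.csv")
        draws.save(pdr)
        artifacts["draws"] = pdr
    subject = data.subject_table([config.stage2_outcome]
                                 + config.stage2_regressors)
    res2 = fit_stage2(subject, draws, config.stage2_spec(),
                      id_col=config.id_column)
    stage2_txt = (
        format_descriptives(subject,
                            [config.stage2_outcome]
                            + config.stage2_regressors, "subject level")
        + "\n" + format_stage2_results(res2))
    p2 = prefix.parent / (prefix.name + "_stage2.txt")
    p2.write_text(stage2_txt)
    artifacts["stage2_report"] = p2
    result.update({"stage2": res2, "draws": draws})
    if verbose:
        print(stage1_txt)
        print(stage2_txt)
    return result
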