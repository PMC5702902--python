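"""Run configuration: a single YAML file validated before any computation.

Top-level sections::

    model:     path: <file> | fixture: <name>; objective: {rid: coef} | rid
    pbpk:      overrides of PBPKParameters fields; doses: [{route, amount_mg, ...}]
    grn:       enabled: bool; overrides of GRNParameters fields; stress: kind
    coupling:  mode, dt_h, duration_h, uniqueness_check, uniqueness_tol,
               feedforward: [{reaction, ki_mm, species, compartment,
                              molar_mass_g_per_mol}],
               feedback: {mode: proportional|lookup, z_ref, breakpoints,
                          interpolation}
    output:    directory
    seed:      int

Unknown keys anywhere are rejected; all problems are reported at once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

from .coupling import (
    CompetitiveInhibition,
    CouplingConfig,
    FeedbackLink,
    FeedforwardLink,
    MultiscaleModel,
    ScalingTable,
)
from .fixtures import FIXTURES
from .grn import GRNParameters, cortisol_schedule
from .io import load_model
from .network import MetabolicNetwork, Objective
from .pbpk import Dose, PBPKParameters

__all__ = ["ConfigError", "RunConfig", "load_config"]

_TOP_KEYS = {"model", "pbpk", "grn", "coupling", "output", "seed"}
_MODEL_KEYS = {"path", "fixture", "objective", "externals"}
_GRN_EXTRA = {"enabled", "stress"}
_COUPLING_KEYS = {"mode", "dt_h", "duration_h", "uniqueness_check",
                  "uniqueness_tol", "feedforward", "feedback"}
_FF_KEYS = {"reaction", "ki_mm", "species", "compartment", "molar_mass_g_per_mol"}
_FB_KEYS = {"mode", "z_ref", "breakpoints", "interpolation"}


class ConfigError(ValueError):
    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


def _check_keys(section: Dict, allowed: set, where: str, problems: List[str]):
    for k in set(section) - allowed:
        problems.append(f"{where}: unknown key {k!r}")


def _field_names(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration, ready to build a MultiscaleModel."""

    raw: Dict[str, Any]
    network: MetabolicNetwork
    objective: Objective
    pbpk_params: PBPKParameters
    grn_params: Optional[GRNParameters]
    stress: str
    coupling: CouplingConfig
    feedforward: List[FeedforwardLink]
    feedback: Optional[FeedbackLink]
    duration_h: float
    output_dir: Path
    seed: int

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def build_model(self) -> MultiscaleModel:
        cortisol = None
        if self.grn_params is not None:
            cortisol = cortisol_schedule(self.stress, self.grn_params)
        return MultiscaleModel(
            network=self.network,
            objective=self.objective,
            pbpk_params=self.pbpk_params,
            grn_params=self.grn_params,
            feedforward=self.feedforward,
            feedback=self.feedback,
            config=self.coupling,
            cortisol=cortisol,
        )


def _parse_objective(spec, network, problems) -> Optional[Objective]:
    if spec is None:
        return None
    if isinstance(spec, str):
        spec = {spec: 1.0}
    if not isinstance(spec, dict):
        problems.append("model.objective must be a reaction id or {rid: coef} map")
        return None
    unknown = set(spec) - set(network.reaction_ids)
    if unknown:
        problems.append(f"model.objective references unknown reactions {sorted(unknown)}")
        return None
    return Objective({k: float(v) for k, v in spec.items()})


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Raises :class:`ConfigError` enumerating every problem found.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    problems: List[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    _check_keys(raw, _TOP_KEYS, "top level", problems)

    # -- model ---------------------------------------------------------
    msec = raw.get("model") or {}
    _check_keys(msec, _MODEL_KEYS, "model", problems)
    network = objective = None
    file_objective = None
    if "path" in msec and "fixture" in msec:
        problems.append("model: give either 'path' or 'fixture', not both")
    elif "path" in msec:
        try:
            network, file_objective = load_model(
                msec["path"], externals=msec.get("externals", ())
            )
        except Exception as exc:
            problems.append(f"model.path: {exc}")
    else:
        name = msec.get("fixture", "mini_liver")
        if name not in FIXTURES:
            problems.append(f"model.fixture: unknown fixture {name!r} "
                            f"(available: {sorted(FIXTURES)})")
        else:
            network, file_objective = FIXTURES[name]()
    if network is not None:
        objective = _parse_objective(msec.get("objective"), network, problems) \
            or file_objective
        if objective is None:
            problems.append("model: no objective in file/fixture and none configured")

    # -- pbpk ----------------------------------------------------------
    psec = dict(raw.get("pbpk") or {})
    dose_spec = psec.pop("doses", None)
    _check_keys(psec, _field_names(PBPKParameters) - {"doses"}, "pbpk", problems)
    pbpk_params = None
    try:
        kwargs = dict(psec)
        if dose_spec is not None:
            kwargs["doses"] = [Dose(**d) for d in dose_spec]
        pbpk_params = PBPKParameters(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"pbpk: {exc}")

    # -- grn -----------------------------------------------------------
    gsec = dict(raw.get("grn") or {})
    enabled = bool(gsec.pop("enabled", True))
    stress = gsec.pop("stress", "homeostatic")
    if stress not in ("homeostatic", "chronic_stress"):
        problems.append(f"grn.stress: unknown schedule {stress!r}")
    _check_keys(gsec, _field_names(GRNParameters), "grn", problems)
    grn_params = None
    if enabled:
        try:
            grn_params = GRNParameters(**gsec)
        except (TypeError, ValueError) as exc:
            problems.append(f"grn: {exc}")

    # -- coupling ------------------------------------------------------
    csec = dict(raw.get("coupling") or {})
    _check_keys(csec, _COUPLING_KEYS, "coupling", problems)
    duration_h = float(csec.pop("duration_h", 24.0))
    ff_spec = csec.pop("feedforward", []) or []
    fb_spec = csec.pop("feedback", None)
    coupling = None
    try:
        coupling = CouplingConfig(**csec)
    except (TypeError, ValueError) as exc:
        problems.append(f"coupling: {exc}")

    feedforward: List[FeedforwardLink] = []
    for i, ff in enumerate(ff_spec):
        _check_keys(ff, _FF_KEYS, f"coupling.feedforward[{i}]", problems)
        try:
            link = FeedforwardLink(
                reaction_id=ff["reaction"],
                transform=CompetitiveInhibition(ki_mm=float(ff.get("ki_mm", 50.0))),
                species=ff.get("species", "metabolite"),
                compartment=ff.get("compartment", "liver"),
                molar_mass_g_per_mol=float(ff.get("molar_mass_g_per_mol", 151.2)),
            )
        except (KeyError, ValueError) as exc:
            problems.append(f"coupling.feedforward[{i}]: {exc}")
            continue
        if network is not None and link.reaction_id not in network.reaction_ids:
            problems.append(
                f"coupling.feedforward[{i}]: unknown reaction {link.reaction_id!r}"
            )
        else:
            feedforward.append(link)

    feedback = None
    if fb_spec is not None:
        _check_keys(fb_spec, _FB_KEYS, "coupling.feedback", problems)
        try:
            bp = [tuple(map(float, b)) for b in fb_spec.get("breakpoints", [])]
            feedback = FeedbackLink(table=ScalingTable(
                mode=fb_spec.get("mode", "proportional"),
                z_ref=fb_spec.get("z_ref"),
                breakpoints=bp,
                interpolation=fb_spec.get("interpolation", "linear"),
            ))
        except ValueError as exc:
            problems.append(f"coupling.feedback: {exc}")
    elif network is not None and objective is not None:
        # default: SF proportional to the reference (wild-type) optimum
        from .network import fba as _fba

        wt = _fba(network, objective)
        if wt.optimal and wt.z > 0:
            feedback = FeedbackLink(table=ScalingTable(mode="proportional",
                                                       z_ref=wt.z))
        else:
            problems.append(
                "coupling.feedback: wild-type objective is not positive; "
                "configure a scaling table explicitly"
            )

    osec = raw.get("output")
    if isinstance(osec, dict):
        _check_keys(osec, {"directory"}, "output", problems)
        out_dir = Path(osec.get("directory", "hepaflux_out"))
    else:
        out_dir = Path(osec or "hepaflux_out")
    seed = int(raw.get("seed", 0))

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        raw=raw, network=network, objective=objective, pbpk_params=pbpk_params,
        grn_params=grn_params, stress=stress, coupling=coupling,
        feedforward=feedforward, feedback=feedback, duration_h=duration_h,
        output_dir=out_dir, seed=seed,
    )
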