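"""Higher-level analysis pipelines composed from the core operations."""

from __future__ import annotations

from typing import List, Optional

from .io import load_model, read_bounds_csv
from .network import (
    EssentialityRecord,
    Objective,
    apply_exchange_bounds,
    essentiality_scan,
)

__all__ = ["gsh_essentiality_screen"]


def gsh_essentiality_screen(
    model_path,
    bounds_csv=None,
    objective: Optional[Objective] = None,
    restrict_to_listed: bool = True,
    influence_threshold: float = 1e-6,
) -> List[EssentialityRecord]:
    """Constrained essentiality screen against a GSH-production objective.

    Loads a liver model (SBML-FBC or tabular, e.g. a user-supplied
    HepatoNet1 file), optionally constrains exchange fluxes with a
    consumption/release bounds table (max-over-observations reduction, with
    unlisted exchanges closed to the physiological set when
    ``restrict_to_listed``), then knocks out each reaction in turn and
    re-evaluates the objective. Returns one record per reaction; the
    influential subset is ``[r for r in records if r.influences_objective]``.
    """
    network, model_objective = load_model(model_path)
    objective = objective or model_objective
    if objective is None:
        raise ValueError("model declares no objective and none was supplied")
    if bounds_csv is not None:
        table = read_bounds_csv(bounds_csv, reduction="max_over_observations")
        network = apply_exchange_bounds(
            network, dict(table.items()), restrict_to_listed=restrict_to_listed
        )
    return essentiality_scan(network, objective,
                             influence_threshold=influence_threshold)
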