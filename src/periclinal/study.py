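"""Assembly of a fully simulated Pinot clone study as a pipeline scenario.

Builds the study design at its published scale: nine clones with selfed
progenies (51 genotyped offspring for the Pinot noir reference clone, 18
or 24 for the others), plus the two grey bud-sport parents and their
sports, which contribute leaf and stem-pith (L2-derived) genotypes but no
progeny.  Tissues and progenies are simulated from the clone layer models;
the canonical haplotype library (SC8_0146_010 phase left unresolved, as in
the references) serves as classification library.
"""

from __future__ import annotations

import numpy as np

from .model import GenotypeTable
from .pinot import (
    CHROMOSOME_LENGTH_BP,
    canonical_library,
    clone_models,
    pinot_panel,
)
from .pipeline import CloneInput, Scenario
from .simulate import SimulationConfig, simulate_clone_tissues, simulate_selfed_progeny

__all__ = ["PROGENY_SIZES", "build_pinot_scenario"]

#: Genotyped selfed-progeny sizes per clone in the study design.
PROGENY_SIZES = {
    "PN162": 51,
    "PG52": 24,
    "PG53": 18,
    "PG3106": 24,
    "PB54": 18,
    "PB55": 18,
    "PB3009": 18,
    "PB3172": 18,
    "PB3232": 24,
}

#: Clones contributing leaf + pith genotypes only (bud-sport analysis).
TISSUE_ONLY_CLONES = ["PGMA19", "PGMA19.S5", "PGMA19.S6", "BCPG9.S7.1", "BCPG9.S7.2"]


def build_pinot_scenario(
    seed: int = 0,
    *,
    genotyping_error_rate: float = 0.0,
) -> Scenario:
    """Simulate the full clone collection and wrap it as a Scenario.

    Deterministic for a given seed.  The truth behind the simulation is
    available from :func:`periclinal.pinot.clone_models`.
    """
    panel = pinot_panel()
    library = canonical_library(concrete_sc8=False)
    by_name = {h.name: h for h in library}
    models = clone_models(concrete_sc8=True)

    clones: list[CloneInput] = []
    for i, (clone_id, n) in enumerate(sorted(PROGENY_SIZES.items())):
        model = models[clone_id]
        leaf, _l2 = simulate_clone_tissues(model, panel)
        leaf.sample_id = clone_id
        config = SimulationConfig(
            n_progeny=n, genotyping_error_rate=genotyping_error_rate, seed=seed
        )
        rng = np.random.default_rng([seed, i])
        progeny = simulate_selfed_progeny(model.L2, config, panel, parent_id=clone_id, rng=rng)
        clones.append(CloneInput(clone_id, leaf=leaf, progeny=progeny))

    for clone_id in TISSUE_ONLY_CLONES:
        model = models[clone_id]
        leaf, l2 = simulate_clone_tissues(model, panel)
        leaf.sample_id = clone_id
        l2.sample_id = clone_id
        clones.append(CloneInput(clone_id, leaf=leaf, l2_tissue=l2))

    return Scenario(
        panel=panel,
        colored_ref=by_name["c188"],
        white_ref=by_name["w216"],
        library=library,
        clones=clones,
        chromosome_length_bp=CHROMOSOME_LENGTH_BP,
    )
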