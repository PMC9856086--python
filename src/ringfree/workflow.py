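"""The iterative repair loop: minimize, measure, branch, bias, repeat.

Each stage is one bounded minimization (default 500 steps) followed by a
long-bond measurement.  The branch decision then goes one of three ways:

* a bond deviates beyond the cutoff  -> biased round: target the worst
  bonds (within the selection window), escalate or build biases, flag the
  neighborhood for soft-core treatment, and minimize again;
* everything is below the cutoff but the stage that just ran was perturbed
  -> unperturbed verification round: strip all biases and soft-core flags
  and minimize once more with the plain potential;
* below the cutoff from an unperturbed stage -> converged; write outputs.

Convergence is therefore only ever certified by an unperturbed stage.  A
clean structure takes the minimum path: one unperturbed stage, no biases
ever built.  To guarantee termination the loop is capped (default 100
stages); the verification round counts against the cap.  Chirality
restraints are generated once from the input structure and stay active
throughout when enabled.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bias_engine, pierce_oracle, stretch_detect
from .charmm_io import (
    MolecularSystem,
    ParameterSet,
    RunConfig,
    read_parameters,
    read_pdb_coords,
    read_psf,
    write_final_coords,
    write_pdb,
)
from .energy_min import EnergyEvaluator, EnergyModel, minimize
from .stretch_detect import bond_deviations, largest_deviation, select_target_bonds
from .topology_graph import build_graph, enumerate_small_rings

__all__ = [
    "Branch",
    "ExitStatus",
    "TraceRow",
    "WorkflowState",
    "LBEResult",
    "decide_branch",
    "run_lbe",
    "longest_bond_trace",
    "write_trace",
    "read_trace",
]

logger = logging.getLogger("ringfree.workflow")


class Branch(enum.Enum):
    DONE = "done"
    UNPERTURBED_ROUND = "unperturbed_round"
    BIASED_ROUND = "biased_round"


class ExitStatus(enum.IntEnum):
    CONVERGED = 0
    STAGE_CAP = 1
    INPUT_ERROR = 2


@dataclass(frozen=True)
class TraceRow:
    """One measurement of the system's longest bond.

    Stage 0 is the input structure before any minimization.
    """

    stage: int
    bond: tuple[int, int]
    deviation: float
    perturbed: bool


@dataclass
class WorkflowState:
    """Loop bookkeeping: stage counter, trace, branch history, bias state."""

    bias_state: bias_engine.BiasState
    stage: int = 0
    trace: list[TraceRow] = field(default_factory=list)
    branches: list[Branch] = field(default_factory=list)
    converged: bool = False
    biases_ever_built: int = 0
    intermediates: list[Path] = field(default_factory=list)


@dataclass
class LBEResult:
    """Final structure, loop state and exit status of a repair run."""

    system: MolecularSystem
    state: WorkflowState
    status: ExitStatus


def decide_branch(
    max_deviation: float, cutoff: float, previous_perturbed: bool
) -> Branch:
    """Three-way branch on the measured worst deviation.

    Deviation at or beyond the cutoff always forces another biased round;
    otherwise a run whose last stage was perturbed must re-verify without
    perturbations before it may finish.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if max_deviation >= cutoff:
        return Branch.BIASED_ROUND
    if previous_perturbed:
        return Branch.UNPERTURBED_ROUND
    return Branch.DONE


def run_lbe(
    config: RunConfig,
    system: MolecularSystem | None = None,
    params: ParameterSet | None = None,
    outdir: str | Path | None = None,
) -> LBEResult:
    """Run the full repair loop.

    Inputs come either from the config's structure/coordinate/parameter
    paths or directly as in-memory objects (fixtures).  Outputs (final
    coordinates, trace, flagged-bond report, optional per-stage snapshots)
    are written when *outdir* or ``config.output_dir`` is set.
    """
    if system is None or params is None:
        if not (config.structure and config.coordinates and config.parameters):
            raise ValueError("config must name structure/coordinates/parameters")
        system = read_psf(config.structure)
        read_pdb_coords(config.coordinates, system)
        params = read_parameters(config.parameters)
    else:
        system = system.copy()
    params.validate_system(system)

    outdir = Path(outdir) if outdir else (
        Path(config.output_dir) if config.output_dir else None
    )
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    model = EnergyModel(
        dielectric=config.dielectric,
        cutoff=config.nonbonded_cutoff,
        switch_on=config.switch_on,
        softcore_delta=config.softcore_delta,
    )
    if config.chirality:
        centers = pierce_oracle.detect_chiral_centers(system)
        model.improper_restraints = pierce_oracle.generate_chirality_restraints(
            centers, system, k=config.chirality_k
        )
        logger.info("restraining %d potential chiral centers", len(centers))

    graph = build_graph(system)
    rings = enumerate_small_rings(graph)
    evaluator = EnergyEvaluator(system, params, model)
    state = WorkflowState(
        bias_state=bias_engine.BiasState(rng=np.random.default_rng(config.seed))
    )

    # trace row 0: the input structure, before any minimization
    report = bond_deviations(system, params)
    rec, dev = largest_deviation(report)
    state.trace.append(TraceRow(stage=0, bond=rec.bond, deviation=dev, perturbed=False))
    logger.info("stage 0 (input): worst bond %s deviation %.3f A", rec.bond, dev)

    perturbed = False  # whether the *upcoming* stage carries perturbations
    status = ExitStatus.STAGE_CAP
    while state.stage < config.max_stages:
        state.stage += 1
        result = minimize(
            system,
            params,
            model,
            steps=config.steps_per_stage,
            flagged=state.bias_state.flagged,
            gtol=config.gradient_tol,
            evaluator=evaluator,
        )
        system = result.system
        evaluator.system = system

        report = bond_deviations(system, params)
        rec, dev = largest_deviation(report)
        state.trace.append(
            TraceRow(stage=state.stage, bond=rec.bond, deviation=dev,
                     perturbed=perturbed)
        )
        if outdir and config.write_intermediates:
            snap = outdir / f"{config.label}-stage{state.stage:03d}.pdb"
            write_pdb(system, snap)
            state.intermediates.append(snap)

        branch = decide_branch(dev, config.cutoff, perturbed)
        state.branches.append(branch)
        logger.info(
            "stage %d: worst bond %s deviation %.3f A -> %s",
            state.stage, rec.bond, dev, branch.value,
        )

        if branch is Branch.DONE:
            state.converged = True
            status = ExitStatus.CONVERGED
            break
        if branch is Branch.UNPERTURBED_ROUND:
            bias_engine.clear_biases(model, state.bias_state)
            perturbed = False
            continue
        # biased round
        targets = select_target_bonds(report, window=config.window,
                                      cutoff=config.cutoff)
        bias_engine.escalate(state.bias_state, rec.bond)
        bias_engine.drop_untargeted(state.bias_state, model, targets)
        bias_engine.build_biases(
            system, targets, graph, rings, state.bias_state, model, config
        )
        state.biases_ever_built += len(targets)
        perturbed = True

    if outdir:
        write_final_coords(system, outdir, label=config.label)
        write_trace(state, outdir / f"{config.label}-trace.tsv")
        stretch_detect.flag_stretched(report, config.cutoff)
        stretch_detect.write_report(report, system,
                                    outdir / f"{config.label}-longbonds.txt")
    return LBEResult(system=system, state=state, status=status)


def longest_bond_trace(state: WorkflowState) -> list[TraceRow]:
    """The per-stage longest-bond table (row 0 = input structure)."""
    return list(state.trace)


def write_trace(state: WorkflowState, path: str | Path) -> None:
    lines = ["stage\tatom_i\tatom_j\tdeviation_A\tperturbed"]
    for row in state.trace:
        lines.append(
            f"{row.stage}\t{row.bond[0]}\t{row.bond[1]}\t"
            f"{row.deviation:.6f}\t{int(row.perturbed)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> list[TraceRow]:
    rows = []
    for line in Path(path).read_text().splitlines()[1:]:
        stage, i, j, dev, pert = line.split("\t")
        rows.append(
            TraceRow(stage=int(stage), bond=(int(i), int(j)),
                     deviation=float(dev), perturbed=bool(int(pert)))
        )
    return rows
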