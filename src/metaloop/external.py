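"""CSV-exchange adapter for external command-line optimizees.

Mirrors the coupling used for agent-based simulators driven from the shell:
the framework writes the individual's parameters to ``params.csv`` (one row
per scalar: ``name,index,value``), invokes the command as a subordinate
process with the exchange directory as working directory, blocks until it
exits, and reads the resulting one-row ``fitness.csv``.
"""

from __future__ import annotations

import shlex
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .evaluation import Optimizee
from .parameters import Individual, ParameterSpec

__all__ = ["write_params_csv", "read_fitness_csv", "run_external", "ExternalOptimizee"]

PARAMS_FILENAME = "params.csv"
FITNESS_FILENAME = "fitness.csv"


def write_params_csv(ind: Individual, path) -> None:
    """One row per scalar parameter: ``name,index,value`` (UTF-8, '.' decimal)."""
    rows = []
    for name, values in ind.values.items():
        for i, v in enumerate(np.atleast_1d(values)):
            rows.append((name, i, float(v)))
    pd.DataFrame(rows, columns=["name", "index", "value"]).to_csv(
        path, index=False, encoding="utf-8")


def read_fitness_csv(path) -> np.ndarray:
    """Read a single row of reals (with or without a header line)."""
    path = Path(path)
    if not path.exists():
        raise EvaluationError(f"fitness file {path} was not produced")
    try:
        df = pd.read_csv(path, header=None)
        values = df.iloc[-1].astype(float).to_numpy()
    except (ValueError, pd.errors.ParserError) as e:
        raise EvaluationError(f"unparsable fitness file {path}: {e}") from e
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise EvaluationError(f"fitness file {path} holds no finite values")
    return values


def run_external(command: str, ind: Individual, workdir) -> np.ndarray:
    """Evaluate one individual through an external command.

    The command is executed with ``workdir`` as its working directory; it is
    expected to read ``params.csv`` there and to write ``fitness.csv`` before
    exiting 0. A nonzero exit or a missing/unparsable fitness file raises
    :class:`EvaluationError` carrying the captured stderr.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    write_params_csv(ind, workdir / PARAMS_FILENAME)
    fitness_path = workdir / FITNESS_FILENAME
    if fitness_path.exists():
        fitness_path.unlink()  # never read a stale result
    proc = subprocess.run(
        shlex.split(command), cwd=workdir, capture_output=True, text=True)
    if proc.returncode != 0:
        raise EvaluationError(
            f"external optimizee {command!r} exited {proc.returncode}; "
            f"stderr:\n{proc.stderr}")
    return read_fitness_csv(fitness_path)


class ExternalOptimizee(Optimizee):
    """Optimizee whose simulation is an external executable.

    Each evaluation runs in its own subdirectory of ``workdir`` (named after
    generation and individual id) so parallel evaluations never collide.
    """

    def __init__(self, command: str, spec: ParameterSpec, workdir):
        self.command = command
        self.spec = spec
        self.workdir = Path(workdir)

    def parameter_spec(self) -> ParameterSpec:
        return self.spec

    def simulate(self, individual: Individual, rng) -> np.ndarray:
        sub = self.workdir / f"g{individual.generation:05d}_i{individual.id:05d}"
        return run_external(self.command, individual, sub)
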