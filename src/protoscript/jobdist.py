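"""Job distributor: the trajectory loop with fail-restart semantics.

For every input structure and every requested output index the distributor
loads a *fresh* pose from disk, seeds the trajectory's random source, and
applies the parsed protocol.  A failed trajectory (mover failure or filter
rejection) restarts the same job from a freshly loaded pose with a new
derived seed, up to ``max_retries`` times; a successful trajectory writes
``<inputstem>_<index:04d>.pdb`` and appends a scorefile row with the total
score, every protocol-level filter's reported value and every mover extra.

Seeds are fully reproducible: job ``k`` (counting over inputs x nstruct)
uses base seed ``seed + k``, and attempt ``a`` of a job uses
``base + 1000*a``.

The command line mirrors the classic invocation::

    protoscript -s input.pdb -parser:protocol dock.xml -nstruct 3 \\
        -seed 7 -out:path out/

(``-database`` is accepted and ignored: all parameters are built in.)
"""

from __future__ import annotations

import argparse
import logging
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ProtoScriptError, ProtocolError
from .packing.taskops import PackerGlobals
from .protocol.base import Status
from .protocol.engine import parse_protocol_text
from .structure.pdbio import read_pdb, write_pdb
from .structure.scorefxn import ScoreFunction, from_profile, score

__all__ = ["RunConfig", "JobResult", "run", "write_scorefile", "main"]

log = logging.getLogger("protoscript")


@dataclass
class RunConfig:
    inputs: list[str]
    protocol_path: str
    nstruct: int = 1
    seed: int = 0
    max_retries: int = 10
    out_dir: str = "."
    scorefile: str = "score.sc"
    extra_density: bool = False
    include_current: bool = False
    database: str | None = None  # accepted and ignored

    def validate(self) -> None:
        if self.nstruct < 1:
            raise ProtocolError("nstruct must be >= 1")
        for path in self.inputs:
            if not os.path.exists(path):
                raise ProtocolError(f"unreadable input structure: {path}")
        if not os.path.exists(self.protocol_path):
            raise ProtocolError(f"unreadable protocol script: {self.protocol_path}")
        Path(self.out_dir).mkdir(parents=True, exist_ok=True)


@dataclass
class JobResult:
    job_id: str
    status: str  # "success" | "failed"
    output_path: str | None
    total_score: float | None
    filter_values: dict[str, float] = field(default_factory=dict)
    mover_extras: dict[str, float] = field(default_factory=dict)
    retries: int = 0


def run(config: RunConfig) -> list[JobResult]:
    """Execute every job; protocol parse errors surface before any job runs."""
    config.validate()
    with open(config.protocol_path) as fh:
        text = fh.read()
    parsed = parse_protocol_text(
        text,
        packer_globals=PackerGlobals(
            extra_density=config.extra_density,
            include_current=config.include_current,
        ),
    )
    score_sfx = from_profile("score12")
    results: list[JobResult] = []
    job_index = 0
    for input_path in config.inputs:
        stem = Path(input_path).stem
        for n in range(1, config.nstruct + 1):
            job_id = f"{stem}_{n:04d}"
            base_seed = config.seed + job_index
            job_index += 1
            result = _run_one_job(
                parsed, input_path, job_id, base_seed, config, score_sfx
            )
            results.append(result)
    write_scorefile(results, os.path.join(config.out_dir, config.scorefile))
    return results


def _run_one_job(
    parsed, input_path: str, job_id: str, base_seed: int, config: RunConfig,
    score_sfx: ScoreFunction,
) -> JobResult:
    for attempt in range(config.max_retries + 1):
        pose = read_pdb(input_path)  # fresh pose per attempt: job isolation
        pose.rng = np.random.default_rng((base_seed + 1000 * attempt) % 2**31)
        log.info("job %s attempt %d (seed %d)", job_id, attempt, base_seed + 1000 * attempt)
        status = parsed.protocol.apply(pose)
        if status is Status.SUCCESS:
            out_path = os.path.join(config.out_dir, f"{job_id}.pdb")
            write_pdb(pose, out_path)
            filter_values = {
                filt.name or filt.key_name: float(filt.report_value(pose))
                for filt in parsed.protocol.filters()
            }
            mover_extras: dict[str, float] = {}
            for mover in parsed.protocol.iter_movers():
                mover_extras.update(mover.extras)
            return JobResult(
                job_id=job_id,
                status="success",
                output_path=out_path,
                total_score=score(pose, score_sfx).total,
                filter_values=filter_values,
                mover_extras=mover_extras,
                retries=attempt,
            )
    log.info("job %s failed after %d attempts", job_id, config.max_retries + 1)
    return JobResult(
        job_id=job_id,
        status="failed",
        output_path=None,
        total_score=None,
        retries=config.max_retries,
    )


def write_scorefile(results: list[JobResult], path: str) -> None:
    """Whitespace-aligned score table, append mode across runs.

    Columns: description, total_score, one per filter instance, one per
    mover extra.  Appending to an existing file with different columns is
    an error.
    """
    columns = ["description", "total_score"]
    for result in results:
        for name in list(result.filter_values) + list(result.mover_extras):
            if name not in columns:
                columns.append(name)
    header_line = None
    if os.path.exists(path):
        with open(path) as fh:
            header_line = fh.readline().rstrip("\n")
    widths = {c: max(len(c), 12) for c in columns}

    def fmt_row(cells: dict[str, str]) -> str:
        return "  ".join(cells.get(c, "-").rjust(widths[c]) for c in columns)

    header = fmt_row({c: c for c in columns})
    if header_line is not None and header_line.split() != header.split():
        raise ProtocolError(
            f"scorefile {path} has columns {header_line.split()}, "
            f"cannot append columns {columns}"
        )
    rows = []
    if header_line is None:
        rows.append(header)
    for result in results:
        if result.status != "success":
            continue
        cells = {"description": result.job_id}
        if result.total_score is not None:
            cells["total_score"] = f"{result.total_score:.3f}"
        for name, value in result.filter_values.items():
            cells[name] = f"{value:.3f}"
        for name, value in result.mover_extras.items():
            cells[name] = f"{value:.3f}"
        rows.append(fmt_row(cells))
    mode = "a" if header_line is not None else "w"
    with open(path, mode) as fh:
        for row in rows:
            fh.write(row + "\n")


def build_arg_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="protoscript",
        description="Run a protocol script over input structures.",
    )
    parser.add_argument(
        "-s", dest="inputs", action="append", required=True,
        help="input PDB file (repeatable)",
    )
    parser.add_argument(
        "-parser:protocol", dest="protocol", required=True,
        help="protocol script file",
    )
    parser.add_argument("-nstruct", dest="nstruct", type=int, default=1)
    parser.add_argument("-seed", dest="seed", type=int, default=0)
    parser.add_argument("-max_retries", dest="max_retries", type=int, default=10)
    parser.add_argument("-out:path", dest="out_dir", default=".")
    parser.add_argument("-out:file:scorefile", dest="scorefile", default="score.sc")
    parser.add_argument(
        "-database", dest="database", default=None,
        help="accepted and ignored (all parameters are built in)",
    )
    parser.add_argument(
        "-packing:extra_density", dest="extra_density", action="store_true"
    )
    parser.add_argument(
        "-packing:include_current", dest="include_current", action="store_true"
    )
    parser.add_argument("-v", "--verbose", action="store_true")
    return parser


def main(argv: list[str] | None = None) -> int:
    args = build_arg_parser().parse_args(argv)
    logging.basicConfig(
        level=logging.INFO if args.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    config = RunConfig(
        inputs=args.inputs,
        protocol_path=args.protocol,
        nstruct=args.nstruct,
        seed=args.seed,
        max_retries=args.max_retries,
        out_dir=args.out_dir,
        scorefile=args.scorefile,
        extra_density=args.extra_density,
        include_current=args.include_current,
        database=args.database,
    )
    try:
        results = run(config)
    except ProtoScriptError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    n_ok = sum(r.status == "success" for r in results)
    print(f"{n_ok}/{len(results)} jobs succeeded; scores in "
          f"{os.path.join(config.out_dir, config.scorefile)}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
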