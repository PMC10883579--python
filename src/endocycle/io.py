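"""State snapshots, restoration and tabular output.

A snapshot is a versioned JSON document carrying the complete simulation
state -- grid, cells (genomes in the v1 text format), lineage log, id
counters and the exact states of every random-number stream -- so that
``restore_state(snapshot_state(pop))`` continues bit-identically to an
uninterrupted run.
"""

from __future__ import annotations

import json
from typing import Any, TextIO

from .cell_cycle import Cell
from .genome import Genome, parse_genome, serialize_genome
from .interference import InterferenceConfig
from .mutation import MutationRates
from .population import Event, Grid, Holobiont, NutrientField, Population
from .regulation import Origin, Stage, StageTable

__all__ = ["SNAPSHOT_VERSION", "snapshot_state", "restore_state", "SnapshotError",
           "write_summary_tsv", "write_events_tsv"]

SNAPSHOT_VERSION = 1


class SnapshotError(ValueError):
    pass


def _cell_to_dict(c: Cell) -> dict[str, Any]:
    return {
        "genome": serialize_genome(c.genome),
        "origin": c.origin.value,
        "expression": "".join("1" if e else "0" for e in c.expression),
        "stage": int(c.stage),
        "passed": [int(s) for s in c.passed],
        "fork": c.fork,
        "alive": c.alive,
        "divided_ready": c.divided_ready,
        "cell_id": c.cell_id,
    }


def _cell_from_dict(d: dict[str, Any]) -> Cell:
    return Cell(
        genome=parse_genome(d["genome"]),
        origin=Origin(d["origin"]),
        expression=tuple(ch == "1" for ch in d["expression"]),
        stage=Stage(d["stage"]),
        passed=tuple(Stage(s) for s in d["passed"]),
        fork=d["fork"],
        alive=d["alive"],
        divided_ready=d["divided_ready"],
        cell_id=d["cell_id"],
    )


def snapshot_state(pop: Population) -> str:
    """Serialize a Population (between steps) to a JSON text document."""
    doc = {
        "version": SNAPSHOT_VERSION,
        "t": pop.t,
        "seed": pop.seed,
        "grid": {"width": pop.grid.width, "height": pop.grid.height},
        "field": {
            "height": pop.field.height,
            "sectors": pop.field.sectors,
            "influx_min": pop.field.influx_min,
            "influx_max": pop.field.influx_max,
        },
        "rho": pop.rho,
        "delta": pop.delta,
        "rates": pop.rates.__dict__,
        "interference": pop.interference.__dict__,
        "stage_patterns": ["".join(map(str, p)) for p in pop.table.patterns],
        "rng": {
            "ecology": pop.rng_ecology.bit_generator.state,
            "binding": pop.rng_binding.bit_generator.state,
            "assay": pop.rng_assay.bit_generator.state,
            "mutation": pop.mutator.rng.bit_generator.state,
        },
        "type_id_next": pop.mutator.counter.next_id,
        "next_hid": pop._next_hid,
        "next_cid": pop._next_cid,
        "holobionts": [
            {
                "site": list(h.site),
                "hid": h.hid,
                "birth_symbiont_count": h.birth_symbiont_count,
                "born_at": h.born_at,
                "host": _cell_to_dict(h.host),
                "symbionts": [_cell_to_dict(s) for s in h.symbionts],
            }
            for h in pop.grid.holobionts()
        ],
        "events": [
            [e.step, e.kind, list(e.site), e.parent_id, e.child_id, e.detail]
            for e in pop.events
        ],
        "cell_parents": {str(k): v for k, v in pop.cell_parents.items()},
        "birth_genomes": {
            str(hid): [serialize_genome(g) for g in gs]
            for hid, gs in pop.birth_genomes.items()
        },
    }
    return json.dumps(doc)


def restore_state(text: str) -> Population:
    """Rebuild a Population from a snapshot document."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SnapshotError(f"unreadable snapshot: {exc}") from exc
    version = doc.get("version")
    if version != SNAPSHOT_VERSION:
        raise SnapshotError(
            f"snapshot version {version!r} not supported (expected {SNAPSHOT_VERSION})"
        )
    required = {"t", "grid", "field", "holobionts", "rng", "events"}
    missing = required - doc.keys()
    if missing:
        raise SnapshotError(f"snapshot missing fields: {sorted(missing)}")

    pop = Population(
        grid=Grid(doc["grid"]["width"], doc["grid"]["height"]),
        fieldspec=NutrientField(**doc["field"]),
        rates=MutationRates(**doc["rates"]),
        interference=InterferenceConfig(**doc["interference"]),
        table=StageTable.from_strings(*doc["stage_patterns"]),
        rho=doc["rho"],
        delta=doc["delta"],
        seed=doc["seed"],
    )
    pop.t = doc["t"]
    pop.rng_ecology.bit_generator.state = doc["rng"]["ecology"]
    pop.rng_binding.bit_generator.state = doc["rng"]["binding"]
    pop.rng_assay.bit_generator.state = doc["rng"]["assay"]
    pop.mutator.rng.bit_generator.state = doc["rng"]["mutation"]
    pop.mutator.counter.next_id = doc["type_id_next"]
    pop._next_hid = doc["next_hid"]
    pop._next_cid = doc["next_cid"]
    for hd in doc["holobionts"]:
        h = Holobiont(
            host=_cell_from_dict(hd["host"]),
            symbionts=[_cell_from_dict(s) for s in hd["symbionts"]],
            site=tuple(hd["site"]),
            hid=hd["hid"],
            birth_symbiont_count=hd["birth_symbiont_count"],
            born_at=hd["born_at"],
        )
        pop.grid.place(h, tuple(hd["site"]))
    pop.events = [
        Event(step, kind, tuple(site), pid, cid, detail)
        for step, kind, site, pid, cid, detail in doc["events"]
    ]
    pop.cell_parents = {int(k): v for k, v in doc.get("cell_parents", {}).items()}
    pop.birth_genomes = {
        int(k): tuple(parse_genome(g) for g in gs)
        for k, gs in doc.get("birth_genomes", {}).items()
    }
    return pop


# -- tabular output ---------------------------------------------------------

def write_summary_tsv(fh: TextIO, rows: list[dict], manifest_hash: str = "") -> None:
    """Population-summary rows as TSV with a manifest header comment."""
    if manifest_hash:
        fh.write(f"# manifest={manifest_hash}\n")
    if not rows:
        return
    scalar_keys = [k for k, v in rows[0].items() if not isinstance(v, (list, tuple))]
    fh.write("\t".join(scalar_keys) + "\n")
    for r in rows:
        fh.write("\t".join(_fmt(r[k]) for k in scalar_keys) + "\n")


def write_events_tsv(fh: TextIO, events: list[Event], manifest_hash: str = "") -> None:
    if manifest_hash:
        fh.write(f"# manifest={manifest_hash}\n")
    fh.write("step\tevent\tx\ty\tparent_id\tchild_id\tdetail\n")
    for e in events:
        fh.write(
            f"{e.step}\t{e.kind}\t{e.site[0]}\t{e.site[1]}\t{e.parent_id}\t{e.child_id}\t{e.detail}\n"
        )


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
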