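"""Connectome tables: reading, validation, and scrubbing.

The substrate of every downstream stage is a :class:`ConnectomeTable` — a neuron
metadata table plus a directed, weighted connection list in the style of a
neuPrint CSV export.  Scrubbing applies the two cleaning rules used throughout
the pipeline: drop connections whose total synapse count ("strength") is below a
minimum (default 6), and drop connections touching a neuron whose transmitter,
type, or id is unknown or invalid.  Transmitters map onto synaptic polarity:
acetylcholine is excitatory; GABA and glutamate act through chloride-permeable
channels and are inhibitory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NeuronClass",
    "Transmitter",
    "Polarity",
    "NeuronRecord",
    "ConnectionRecord",
    "ConnectomeTable",
    "ScrubReport",
    "FormatError",
    "ValidationError",
    "read_neurons",
    "read_connections",
    "write_neurons",
    "write_connections",
    "scrub",
    "polarity_of",
]


class FormatError(ValueError):
    """A file does not follow the expected CSV schema."""


class ValidationError(ValueError):
    """Table contents violate an invariant (duplicate ids, bad weights, ...)."""


class NeuronClass(str, Enum):
    DN = "DN"
    AN = "AN"
    IN = "IN"
    MN = "MN"
    OTHER = "other"


class Transmitter(str, Enum):
    ACETYLCHOLINE = "acetylcholine"
    GABA = "gaba"
    GLUTAMATE = "glutamate"
    UNKNOWN = "unknown"


class Polarity(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"


#: Accepted spellings for each transmitter, lowercased.
_TRANSMITTER_ALIASES: Mapping[str, Transmitter] = {
    "acetylcholine": Transmitter.ACETYLCHOLINE,
    "ach": Transmitter.ACETYLCHOLINE,
    "cholinergic": Transmitter.ACETYLCHOLINE,
    "gaba": Transmitter.GABA,
    "gabaergic": Transmitter.GABA,
    "glutamate": Transmitter.GLUTAMATE,
    "glut": Transmitter.GLUTAMATE,
    "glutamatergic": Transmitter.GLUTAMATE,
    "unknown": Transmitter.UNKNOWN,
    "": Transmitter.UNKNOWN,
    "nan": Transmitter.UNKNOWN,
    "none": Transmitter.UNKNOWN,
}

_CLASS_ALIASES: Mapping[str, NeuronClass] = {
    "dn": NeuronClass.DN,
    "an": NeuronClass.AN,
    "in": NeuronClass.IN,
    "mn": NeuronClass.MN,
    "descending": NeuronClass.DN,
    "ascending": NeuronClass.AN,
    "interneuron": NeuronClass.IN,
    "intrinsic": NeuronClass.IN,
    "motor": NeuronClass.MN,
}

_SIDES = {"L", "R", "midline", "unknown"}


@dataclass(frozen=True)
class NeuronRecord:
    """One neuron's metadata row.

    ``type_label`` is the connectome cell-type name (e.g. ``DNp01``,
    ``AN08B098``); all copies of a type share it, so type-level grouping pools
    left/right mirror twins.
    """

    neuron_id: int
    neuron_class: NeuronClass
    type_label: str
    transmitter: Transmitter = Transmitter.UNKNOWN
    side: str = "unknown"

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValidationError(f"invalid side {self.side!r} for neuron {self.neuron_id}")


@dataclass(frozen=True)
class ConnectionRecord:
    """A directed neuron-pair connection; weight is the summed synapse count."""

    pre_id: int
    post_id: int
    weight: int

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValidationError(
                f"connection ({self.pre_id}, {self.post_id}) has non-positive weight {self.weight}"
            )


@dataclass
class ConnectomeTable:
    """Neuron metadata plus an aggregated directed connection list."""

    neurons: list[NeuronRecord]
    connections: list[ConnectionRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.neuron_id for n in self.neurons]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate neuron ids: {dupes[:5]}")
        known = set(ids)
        for c in self.connections:
            if c.pre_id not in known or c.post_id not in known:
                raise ValidationError(
                    f"connection ({c.pre_id}, {c.post_id}) references an unknown neuron"
                )

    # -- convenience accessors -------------------------------------------------
    def neuron_by_id(self) -> dict[int, NeuronRecord]:
        return {n.neuron_id: n for n in self.neurons}

    def neurons_of_class(self, cls: NeuronClass) -> list[NeuronRecord]:
        return [n for n in self.neurons if n.neuron_class is cls]

    def connections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.pre_id, c.post_id, c.weight) for c in self.connections],
            columns=["pre_id", "post_id", "weight"],
        )

    def neurons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (n.neuron_id, n.neuron_class.value, n.type_label, n.transmitter.value, n.side)
                for n in self.neurons
            ],
            columns=["neuron_id", "class", "type", "transmitter", "side"],
        )


@dataclass
class ScrubReport:
    """Tallies from one scrub pass; kept + dropped conserves the input count."""

    n_neurons_kept: int
    n_connections_kept: int
    n_excitatory: int
    n_inhibitory: int
    n_dropped_by_reason: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_excitatory + self.n_inhibitory != self.n_connections_kept:
            raise ValidationError("polarity counts do not sum to kept connections")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def polarity_of(transmitter: Transmitter) -> Polarity:
    """Map a transmitter to its synaptic polarity.

    Cholinergic (nicotinic) receptors are excitatory; GABA_A and GluCl receptors
    are chloride channels and inhibitory.  ``unknown`` has no polarity — scrub
    first.
    """
    if transmitter is Transmitter.ACETYLCHOLINE:
        return Polarity.EXCITATORY
    if transmitter in (Transmitter.GABA, Transmitter.GLUTAMATE):
        return Polarity.INHIBITORY
    raise ValueError(f"no polarity for transmitter {transmitter!r}; scrub unknowns first")


def _normalize_transmitter(raw: object) -> Transmitter:
    key = str(raw).strip().lower()
    return _TRANSMITTER_ALIASES.get(key, Transmitter.UNKNOWN)


def _normalize_class(raw: object) -> NeuronClass:
    key = str(raw).strip().lower()
    return _CLASS_ALIASES.get(key, NeuronClass.OTHER)


def read_neurons(path: str | Path) -> list[NeuronRecord]:
    """Read a neuron metadata CSV (``neuron_id,class,type,transmitter,side``).

    ``side`` is optional and defaults to ``unknown``; blank or unrecognised
    transmitters map to ``unknown``; class labels are normalised to the
    DN/AN/IN/MN/other enumeration.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"neuron_id", "class", "type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"neuron table {path} missing column(s): {sorted(missing)}")
    if "transmitter" not in df.columns:
        df["transmitter"] = "unknown"
    if "side" not in df.columns:
        df["side"] = "unknown"
    df = df.rename(columns={"class": "neuron_class"})

    records: list[NeuronRecord] = []
    seen: set[int] = set()
    for row in df.itertuples(index=False):
        try:
            nid = int(row.neuron_id)
        except ValueError as exc:
            raise FormatError(f"non-integer neuron_id {row.neuron_id!r}") from exc
        if nid in seen:
            raise ValidationError(f"duplicate neuron_id {nid}")
        seen.add(nid)
        side = str(row.side).strip() or "unknown"
        if side not in _SIDES:
            side = "unknown"
        records.append(
            NeuronRecord(
                neuron_id=nid,
                neuron_class=_normalize_class(row.neuron_class),
                type_label=str(row.type).strip(),
                transmitter=_normalize_transmitter(row.transmitter),
                side=side,
            )
        )
    return records


def read_connections(path: str | Path) -> list[ConnectionRecord]:
    """Read a connection CSV (``pre_id,post_id,weight``), summing duplicates.

    Repeated ``(pre, post)`` rows are aggregated into one record with the summed
    weight, so the strength filter downstream always sees total strength.
    """
    df = pd.read_csv(path)
    required = {"pre_id", "post_id", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"connection table {path} missing column(s): {sorted(missing)}")
    if (df["weight"] <= 0).any():
        bad = df.loc[df["weight"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive weight {bad['weight']} on ({bad['pre_id']}, {bad['post_id']})"
        )
    agg = df.groupby(["pre_id", "post_id"], sort=True, as_index=False)["weight"].sum()
    return [
        ConnectionRecord(int(r.pre_id), int(r.post_id), int(r.weight))
        for r in agg.itertuples(index=False)
    ]


def write_neurons(neurons: Iterable[NeuronRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (n.neuron_id, n.neuron_class.value, n.type_label, n.transmitter.value, n.side)
            for n in neurons
        ],
        columns=["neuron_id", "class", "type", "transmitter", "side"],
    ).to_csv(path, index=False)


def write_connections(connections: Iterable[ConnectionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(c.pre_id, c.post_id, c.weight) for c in connections],
        columns=["pre_id", "post_id", "weight"],
    ).to_csv(path, index=False)


def scrub(
    table: ConnectomeTable, min_strength: int = 6
) -> tuple[ConnectomeTable, ScrubReport]:
    """Apply the cleaning rules and tally what was dropped.

    Drops, in order of reason precedence: connections with total strength below
    ``min_strength``; connections touching a neuron with an unknown transmitter;
    connections touching a neuron with a blank/invalid type label.  Neurons left
    without connections stay in the neuron table (graph builders exclude
    isolated nodes themselves).  Idempotent.
    """
    by_id = table.neuron_by_id()
    kept: list[ConnectionRecord] = []
    dropped: dict[str, int] = {}
    n_exc = n_inh = 0

    def _drop(reason: str) -> None:
        dropped[reason] = dropped.get(reason, 0) + 1

    for c in table.connections:
        pre = by_id[c.pre_id]
        post = by_id[c.post_id]
        if c.weight < min_strength:
            _drop("below_strength")
            continue
        if pre.transmitter is Transmitter.UNKNOWN or post.transmitter is Transmitter.UNKNOWN:
            _drop("unknown_transmitter")
            continue
        if not pre.type_label or not post.type_label:
            _drop("invalid_type")
            continue
        kept.append(c)
        if polarity_of(pre.transmitter) is Polarity.EXCITATORY:
            n_exc += 1
        else:
            n_inh += 1

    provenance = dict(table.provenance)
    provenance["scrub"] = {"min_strength": min_strength}
    scrubbed = ConnectomeTable(
        neurons=list(table.neurons), connections=kept, provenance=provenance
    )
    report = ScrubReport(
        n_neurons_kept=len(table.neurons),
        n_connections_kept=len(kept),
        n_excitatory=n_exc,
        n_inhibitory=n_inh,
        n_dropped_by_reason=dropped,
    )
    return scrubbed, report


def load_table(
    neurons_path: str | Path, connections_path: str | Path, source: str = ""
) -> ConnectomeTable:
    """Read both CSVs into an (unscrubbed) table with a provenance tag."""
    return ConnectomeTable(
        neurons=read_neurons(neurons_path),
        connections=read_connections(connections_path),
        provenance={"source": source or str(neurons_path)},
    )
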