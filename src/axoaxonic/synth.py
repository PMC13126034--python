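"""Seeded synthetic connectomes with the statistical structure of the fly VNC
axo-axonic network.

The generator emulates, at a few-hundred-neuron scale, the features the
analysis stages depend on: ~1% pair sparsity per motif (DN→DN 0.010,
AN→DN 0.012, IN→DN 0.007 of ordered pairs), a skewed synapse-count law with
minimum 6 (so every generated edge survives the strength scrub), motif-dependent
transmitter proportions (~90% cholinergic for homotypic DN→DN, ~60% for
heterotypic, ~50/50 for AN→DN and IN→DN), left/right mirror pairing with an
elevated connection rate between mirror twins (the matrix diagonal), a planted
high-in-degree hub pair (the giant-fiber analog, ~97 distinct presynaptic
partners each), and a planted octet of near-exclusive cholinergic ascending
neurons whose strongest output targets the hub type and whose off-target
connections stay below 15 synapses.

Edge counts per motif are drawn binomially at the configured density and the
planted structure is carved out of that budget, so realized densities stay
within binomial sampling error of the configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome import (
    ConnectionRecord,
    ConnectomeTable,
    NeuronClass,
    NeuronRecord,
    Transmitter,
)

__all__ = ["GeneratorConfig", "GroundTruth", "ConfigError", "generate", "generate_skeletons", "validate"]


class ConfigError(ValueError):
    """Generator configuration is infeasible."""


@dataclass
class GeneratorConfig:
    # class sizes
    n_dn: int = 300
    n_an: int = 120
    n_in: int = 80
    # ordered-pair connection probability per motif
    density_dn_dn: float = 0.010
    density_an_dn: float = 0.012
    density_in_dn: float = 0.007
    # synapse-count law: shifted geometric on {6, 7, ...}; p chosen so the
    # median weight is ~10
    weight_min: int = 6
    weight_geom_p: float = 1.0 - 0.5 ** 0.25
    # connection-level cholinergic fractions per motif context
    homotypic_cholinergic: float = 0.9   # realized via mirror-pair transmitters
    heterotypic_cholinergic: float = 0.6
    an_dn_cholinergic: float = 0.5
    in_dn_cholinergic: float = 0.5
    # mirror pairing
    mirror_fraction: float = 0.9          # fraction of neurons with an L/R twin
    mirror_connection_prob: float = 0.35  # per direction, per mirror DN pair
    # planted giant-fiber-like hub (two mirror DNs sharing one type label)
    hub_partner_count: int = 97           # target distinct presynaptic partners per hub
    hub_type: str = "DNp01"
    # planted exclusive octet of ascending neurons
    octet_size: int = 8
    octet_type: str = "AN08B098"
    octet_hub_weight: tuple[int, int] = (80, 120)     # strong edge to primary hub
    octet_second_hub_weight: tuple[int, int] = (20, 40)
    octet_max_offtargets: int = 2
    octet_offtarget_weight: tuple[int, int] = (6, 14)  # below the 15-synapse cap
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.density_dn_dn, self.density_an_dn, self.density_in_dn):
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"density {d} outside [0, 1]")
        if self.weight_min < 1:
            raise ConfigError("weight_min must be >= 1")
        if self.octet_size and self.octet_size > self.n_an:
            raise ConfigError("octet larger than the AN population")
        pool = self.n_dn + self.n_an + self.n_in - 2
        if self.hub_partner_count and self.hub_partner_count > pool:
            raise ConfigError(
                f"hub partner count {self.hub_partner_count} exceeds presynaptic pool {pool}"
            )


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    hub_ids: list[int]
    octet_ids: list[int]
    planted_densities: dict[str, float]
    mirror_map: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "hub_ids": self.hub_ids,
                    "octet_ids": self.octet_ids,
                    "planted_densities": self.planted_densities,
                    "mirror_map": {str(k): v for k, v in self.mirror_map.items()},
                },
                indent=2,
            )
        )


def _draw_weight(rng: np.random.Generator, cfg: GeneratorConfig, size: int = 1) -> np.ndarray:
    return cfg.weight_min + rng.geometric(cfg.weight_geom_p, size=size) - 1


def _make_population(cfg: GeneratorConfig, rng: np.random.Generator):
    """Neuron records plus bookkeeping pools."""
    neurons: list[NeuronRecord] = []
    mirror_map: dict[int, int] = {}

    def _pair_types(n: int, base: int, prefix: str, cls: NeuronClass, chol_frac: float,
                    first_type: str | None = None, first_trans: Transmitter | None = None):
        """Lay out `n` neurons: mirrored pairs first, singletons after."""
        n_pairs = int(n * cfg.mirror_fraction) // 2
        ids = [base + i for i in range(n)]
        i = 0
        pair_idx = 0
        while pair_idx < n_pairs:
            a, b = ids[i], ids[i + 1]
            if pair_idx == 0 and first_type is not None:
                tlabel, trans = first_type, first_trans
            else:
                tlabel = f"{prefix}{pair_idx:03d}"
                trans = _draw_transmitter(rng, chol_frac)
            neurons.append(NeuronRecord(a, cls, tlabel, trans, "L"))
            neurons.append(NeuronRecord(b, cls, tlabel, trans, "R"))
            mirror_map[a] = b
            mirror_map[b] = a
            i += 2
            pair_idx += 1
        j = 0
        while i < n:
            tlabel = f"{prefix}s{j:03d}"
            trans = _draw_transmitter(rng, chol_frac)
            side = "L" if rng.random() < 0.5 else "R"
            neurons.append(NeuronRecord(ids[i], cls, tlabel, trans, side))
            i += 1
            j += 1
        return ids

    def _draw_transmitter(rng: np.random.Generator, chol_frac: float) -> Transmitter:
        if rng.random() < chol_frac:
            return Transmitter.ACETYLCHOLINE
        return Transmitter.GABA if rng.random() < 0.5 else Transmitter.GLUTAMATE

    # DNs: mirror-pair transmitters drawn at the homotypic cholinergic fraction,
    # so diagonal (homotypic) edges inherit ~90% cholinergic pres.
    dn_ids = _pair_types(
        cfg.n_dn, 10_000, "DN", NeuronClass.DN, cfg.homotypic_cholinergic,
        first_type=cfg.hub_type if cfg.hub_partner_count else None,
        first_trans=Transmitter.ACETYLCHOLINE,
    )
    an_ids = _pair_types(cfg.n_an, 20_000, "AN", NeuronClass.AN, cfg.an_dn_cholinergic)
    in_ids = _pair_types(cfg.n_in, 30_000, "IN", NeuronClass.IN, cfg.in_dn_cholinergic)

    # Octet: overwrite the first 8 AN records with the planted exclusive type.
    octet_ids: list[int] = []
    if cfg.octet_size:
        octet_ids = an_ids[: cfg.octet_size]
        by_id = {n.neuron_id: k for k, n in enumerate(neurons)}
        for k, oid in enumerate(octet_ids):
            old = neurons[by_id[oid]]
            neurons[by_id[oid]] = NeuronRecord(
                oid, NeuronClass.AN, cfg.octet_type, Transmitter.ACETYLCHOLINE,
                "L" if k % 2 == 0 else "R",
            )
    hub_ids = [
        n.neuron_id for n in neurons
        if n.type_label == cfg.hub_type and n.neuron_class is NeuronClass.DN
    ]
    return neurons, dn_ids, an_ids, in_ids, hub_ids, octet_ids, mirror_map


def generate(config: GeneratorConfig | None = None) -> tuple[ConnectomeTable, GroundTruth]:
    """Generate a synthetic connectome table plus its planted ground truth.

    Deterministic given ``config.seed``: two calls with the same configuration
    emit identical tables.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    neurons, dn_ids, an_ids, in_ids, hub_ids, octet_ids, mirror_map = _make_population(cfg, rng)
    by_id = {n.neuron_id: n for n in neurons}

    edges: dict[tuple[int, int], int] = {}

    def _add(pre: int, post: int, w: int) -> bool:
        if pre == post or (pre, post) in edges:
            return False
        edges[(pre, post)] = int(w)
        return True

    # ---- planted structure ---------------------------------------------------
    # mirror-twin (homotypic) DN edges: the Fig-4A-style diagonal
    dn_pairs = sorted(
        {tuple(sorted((a, b))) for a, b in mirror_map.items() if by_id[a].neuron_class is NeuronClass.DN}
    )
    for a, b in dn_pairs:
        if rng.random() < cfg.mirror_connection_prob:
            _add(a, b, _draw_weight(rng, cfg)[0])
        if rng.random() < cfg.mirror_connection_prob:
            _add(b, a, _draw_weight(rng, cfg)[0])

    # exclusive octet: strong edge to the nearer hub, weaker to the far one,
    # and at most `octet_max_offtargets` sub-cap off-target edges
    non_hub_dns = [i for i in dn_ids if i not in hub_ids]
    for k, oid in enumerate(octet_ids):
        if not hub_ids:
            break
        primary = hub_ids[k % len(hub_ids)]
        _add(oid, primary, rng.integers(*cfg.octet_hub_weight, endpoint=True))
        if len(hub_ids) > 1:
            secondary = hub_ids[(k + 1) % len(hub_ids)]
            _add(oid, secondary, rng.integers(*cfg.octet_second_hub_weight, endpoint=True))
        n_off = rng.integers(0, cfg.octet_max_offtargets, endpoint=True)
        for t in rng.choice(non_hub_dns, size=n_off, replace=False):
            _add(oid, int(t), rng.integers(*cfg.octet_offtarget_weight, endpoint=True))

    # hub in-partners: each candidate presynaptic neuron independently, at a
    # rate that tops the planted octet/mirror partners up to ~hub_partner_count
    if cfg.hub_partner_count and hub_ids:
        all_ids = dn_ids + an_ids + in_ids
        for hub in hub_ids:
            existing = {p for (p, q) in edges if q == hub}
            pool = [i for i in all_ids if i != hub and i not in existing and i not in hub_ids]
            want = max(0, cfg.hub_partner_count - len(existing))
            p = min(1.0, want / len(pool)) if pool else 0.0
            mask = rng.random(len(pool)) < p
            chosen = [pid for pid, m in zip(pool, mask) if m]
            for pid in chosen:
                _add(pid, hub, _draw_weight(rng, cfg)[0])

    # ---- background edges, filling each motif's binomial budget --------------
    chol_dns = [i for i in dn_ids if by_id[i].transmitter is Transmitter.ACETYLCHOLINE]
    inh_dns = [i for i in dn_ids if by_id[i].transmitter is not Transmitter.ACETYLCHOLINE]
    bg_posts = [i for i in dn_ids if i not in hub_ids]

    def _count_motif(pre_cls: NeuronClass) -> int:
        return sum(
            1 for (p, q) in edges
            if by_id[p].neuron_class is pre_cls and by_id[q].neuron_class is NeuronClass.DN
        )

    def _fill(pre_cls: NeuronClass, n_pre: int, density: float, pick_pre) -> None:
        n_pairs = n_pre * cfg.n_dn - (cfg.n_dn if pre_cls is NeuronClass.DN else 0)
        target = int(rng.binomial(n_pairs, density)) if density > 0 else 0
        need = target - _count_motif(pre_cls)
        attempts = 0
        while need > 0 and attempts < 50 * target + 1000:
            attempts += 1
            pre = pick_pre()
            post = int(rng.choice(bg_posts))
            if by_id[pre].neuron_class is NeuronClass.DN and by_id[post].type_label == by_id[pre].type_label:
                continue  # homotypic background suppressed; the diagonal is planted
            if _add(pre, post, _draw_weight(rng, cfg)[0]):
                need -= 1

    def _pick_dn_pre() -> int:
        # heterotypic transmitter mix: cholinergic pre with the configured odds
        if inh_dns and rng.random() >= cfg.heterotypic_cholinergic:
            return int(rng.choice(inh_dns))
        return int(rng.choice(chol_dns)) if chol_dns else int(rng.choice(dn_ids))

    bg_ans = [i for i in an_ids if i not in octet_ids]
    _fill(NeuronClass.DN, cfg.n_dn, cfg.density_dn_dn, _pick_dn_pre)
    if bg_ans:
        _fill(NeuronClass.AN, cfg.n_an, cfg.density_an_dn, lambda: int(rng.choice(bg_ans)))
    _fill(NeuronClass.IN, cfg.n_in, cfg.density_in_dn, lambda: int(rng.choice(in_ids)))

    connections = [
        ConnectionRecord(p, q, w) for (p, q), w in sorted(edges.items())
    ]
    table = ConnectomeTable(
        neurons=neurons,
        connections=connections,
        provenance={"source": "synthetic", "seed": cfg.seed},
    )
    n_dn_dn = _count_motif(NeuronClass.DN)
    n_an_dn = _count_motif(NeuronClass.AN)
    n_in_dn = _count_motif(NeuronClass.IN)
    truth = GroundTruth(
        hub_ids=hub_ids,
        octet_ids=list(octet_ids),
        planted_densities={
            "DN->DN": n_dn_dn / max(1, cfg.n_dn * (cfg.n_dn - 1)),
            "AN->DN": n_an_dn / max(1, cfg.n_an * cfg.n_dn),
            "IN->DN": n_in_dn / max(1, cfg.n_in * cfg.n_dn),
        },
        mirror_map=mirror_map,
    )
    return table, truth


# ---------------------------------------------------------------------------
# skeletons
# ---------------------------------------------------------------------------

def generate_skeletons(
    table: ConnectomeTable,
    out_dir: str | Path,
    seed: int = 0,
    correlation: float = 0.95,
    mean_length: float = 1000.0,
    sd_length: float = 300.0,
    n_segments: int = 20,
) -> dict[int, float]:
    """Write one synthetic SWC skeleton per DN; return ground-truth cable lengths.

    Cable length is drawn so that, across the DN population, Pearson correlation
    with total input strength approaches ``correlation``.  Each skeleton is a
    random branching tree whose segment lengths sum exactly to the drawn total.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    strength: dict[int, float] = {}
    for c in table.connections:
        strength[c.post_id] = strength.get(c.post_id, 0.0) + c.weight
    dns = [n.neuron_id for n in table.neurons if n.neuron_class is NeuronClass.DN]
    s = np.array([strength.get(i, 0.0) for i in dns], dtype=float)
    if len(dns) == 0:
        return {}
    sx = (s - s.mean()) / (s.std() if s.std() > 0 else 1.0)
    z = rng.standard_normal(len(dns))
    y = correlation * sx + math.sqrt(max(0.0, 1.0 - correlation ** 2)) * z
    lengths = np.clip(mean_length + sd_length * y, 50.0, None)

    truth: dict[int, float] = {}
    for nid, total in zip(dns, lengths):
        truth[nid] = float(total)
        _write_random_tree(out / f"{nid}.swc", float(total), n_segments, rng)
    return truth


def _write_random_tree(path: Path, total_length: float, n_segments: int, rng: np.random.Generator) -> None:
    seg = total_length / n_segments
    xyz = [np.zeros(3)]
    parents = [-1]
    for _ in range(n_segments):
        parent = int(rng.integers(0, len(xyz)))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        xyz.append(xyz[parent] + seg * direction)
        parents.append(parent)
    lines = ["# synthetic skeleton (randomly branched tree)"]
    for i, (p, pt) in enumerate(zip(parents, xyz)):
        swc_parent = -1 if p == -1 else p + 1
        lines.append(f"{i + 1} 0 {pt[0]:.4f} {pt[1]:.4f} {pt[2]:.4f} 0.5 {swc_parent}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# self-checks
# ---------------------------------------------------------------------------

def validate(table: ConnectomeTable, config: GeneratorConfig, n_se: float = 5.0) -> dict:
    """Compare realized statistics against the generator configuration.

    Checks per-motif ordered-pair density (within ``n_se`` binomial standard
    errors), the weight floor, and per-motif cholinergic connection fractions
    (within ``n_se`` binomial SEs of the configured mix, with a 0.05 floor on
    the tolerance).  Returns a report dict with an overall ``ok`` flag.
    """
    by_id = table.neuron_by_id()
    checks: dict[str, dict] = {}

    def _motif_edges(pre_cls: NeuronClass):
        return [
            c for c in table.connections
            if by_id[c.pre_id].neuron_class is pre_cls
            and by_id[c.post_id].neuron_class is NeuronClass.DN
        ]

    motifs = [
        ("DN->DN", NeuronClass.DN, config.n_dn * max(0, config.n_dn - 1), config.density_dn_dn, None),
        ("AN->DN", NeuronClass.AN, config.n_an * config.n_dn, config.density_an_dn, config.an_dn_cholinergic),
        ("IN->DN", NeuronClass.IN, config.n_in * config.n_dn, config.density_in_dn, config.in_dn_cholinergic),
    ]
    for name, cls, n_pairs, density, chol in motifs:
        es = _motif_edges(cls)
        realized = len(es) / n_pairs if n_pairs else 0.0
        se = math.sqrt(density * (1 - density) / n_pairs) if n_pairs else 0.0
        checks[f"density_{name}"] = {
            "target": density,
            "realized": realized,
            "ok": abs(realized - density) <= n_se * se + 1e-12,
        }
        if chol is not None and es:
            frac = sum(
                1 for c in es if by_id[c.pre_id].transmitter is Transmitter.ACETYLCHOLINE
            ) / len(es)
            # edges cluster on presynaptic neurons, so the binomial unit is the
            # distinct presynaptic neuron, not the edge
            n_pre = len({c.pre_id for c in es})
            tol = max(0.05, n_se * math.sqrt(chol * (1 - chol) / n_pre))
            checks[f"cholinergic_{name}"] = {
                "target": chol,
                "realized": frac,
                "ok": abs(frac - chol) <= tol,
            }

    weights_ok = all(c.weight >= config.weight_min for c in table.connections)
    checks["weight_floor"] = {"target": config.weight_min, "ok": weights_ok}

    report = {"checks": checks, "ok": all(c["ok"] for c in checks.values())}
    return report
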