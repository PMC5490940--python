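"""Plain-text readers/writers shared across the pipeline.

Formats: ligand TSV (``protein_id <tab> fp_hex`` with hex-packed bitsets,
or ``protein_id <tab> molecule`` strings fingerprinted on load), seed
lists (one id per line), and an NPZ cache for influence matrices keyed by
graph hash and beta.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome import InfluenceMatrix, influence_matrix
from .ligand_sea import FingerprintSet, fingerprint_molecules

__all__ = [
    "fp_to_hex",
    "hex_to_fp",
    "write_ligand_sets",
    "read_ligand_sets",
    "read_seed_list",
    "write_seed_list",
    "cached_influence_matrix",
]


def fp_to_hex(fp: np.ndarray) -> str:
    return np.packbits(np.asarray(fp, dtype=bool)).tobytes().hex()


def hex_to_fp(s: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def write_ligand_sets(sets: dict, path) -> None:
    """Write protein fingerprint sets as `protein_id <tab> fp_hex` lines."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tfp_hex\n")
        for pid in sorted(sets):
            for fp in sets[pid].fingerprints:
                fh.write(f"{pid}\t{fp_to_hex(fp)}\n")


def read_ligand_sets(path, n_bits: int = 1024, molecules: bool = False) -> dict:
    """Read ligand TSV into protein -> FingerprintSet.

    With ``molecules=True`` the second column holds molecule strings that
    are fingerprinted with the default hashed backend instead of hex
    bitsets.
    """
    per: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, payload = line.split("\t")[:2]
            per.setdefault(pid, []).append(payload)
    out = {}
    for pid, items in per.items():
        if molecules:
            fps = fingerprint_molecules(items, n_bits=n_bits)
        else:
            fps = np.stack([hex_to_fp(h, n_bits) for h in items])
        out[pid] = FingerprintSet(protein_id=pid, fingerprints=fps)
    return out


def read_seed_list(path) -> set:
    with open(path) as fh:
        return {
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        }


def write_seed_list(seeds, path) -> None:
    with open(path, "w") as fh:
        for s in sorted(seeds):
            fh.write(f"{s}\n")


def _graph_hash(graph: nx.Graph) -> str:
    payload = "\n".join(
        f"{a}\t{b}" for a, b in sorted(tuple(sorted(map(str, e))) for e in graph.edges)
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cached_influence_matrix(graph: nx.Graph, beta: float, cache_dir) -> InfluenceMatrix:
    """Influence matrix with an NPZ disk cache keyed by graph hash and beta.

    Recomputing the kernel dominates repeated screens of the same network;
    the cache key covers the edge set and beta, so a changed network never
    reuses a stale kernel.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"influence_{_graph_hash(graph)}_beta{beta:.6f}.npz"
    path = cache_dir / key
    if path.exists():
        with np.load(path, allow_pickle=False) as z:
            return InfluenceMatrix(F=z["F"], beta=float(z["beta"]), nodes=list(z["nodes"]))
    F = influence_matrix(graph, beta=beta)
    np.savez_compressed(path, F=F.F, beta=F.beta, nodes=np.array(F.nodes, dtype=str))
    return F
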