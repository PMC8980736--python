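"""Batch virtual screening against one pocket.

Featurizes each library molecule, predicts its 92-value target vector
with a trained surrogate, filters by Lipinski's rule of five and ranks
by predicted pK (descending, stable in input order on ties). The
intended use mirrors large-library screening: featurize -> predict ->
rank -> take the top k for follow-up docking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski as RDLipinski

from . import targets as tg
from .ligand import MAX_ATOMS, MoleculeGraph, SmilesRecord, encode_ligand, \
    iter_smiles_records, prune_ligand
from .model import predict_batch
from .pocket import PocketGrid

__all__ = [
    "ScreeningRecord",
    "lipinski_violations",
    "molecule_properties",
    "screen",
    "top_k",
    "records_to_tsv",
]

_TSV_COLUMNS = ("rank", "id", "smiles", "pred_pK",
                "pred_min_E_without_VDWR", "lipinski_violations", "flags")


@dataclass
class ScreeningRecord:
    """One library molecule with its predictions, filters and rank."""

    mol_id: str
    smiles: str
    pred_pk: float | None = None
    pred_min_e: float | None = None
    lipinski_violations: int | None = None
    flags: list[str] = field(default_factory=list)
    rank: int | None = None
    logp_source: str | None = None  # "library" | "computed"

    @property
    def ok(self) -> bool:
        return self.pred_pk is not None


def lipinski_violations(mw: float | None, logp: float | None,
                        donors: float | None, acceptors: float | None
                        ) -> tuple[int, list[str]]:
    """Count rule-of-five violations; boundary values are compliant.

    Returns ``(count, missing)`` where ``missing`` names properties that
    could not be evaluated (these are flagged, never counted as
    violations).
    """
    count = 0
    missing: list[str] = []
    for name, value, limit in (("MW", mw, 500.0), ("logP", logp, 5.0),
                               ("HBD", donors, 5.0), ("HBA", acceptors, 10.0)):
        if value is None or not np.isfinite(value):
            missing.append(name)
        elif value > limit:
            count += 1
    return count, missing


def molecule_properties(smiles: str) -> dict[str, float] | None:
    """MW, logP (Crippen), H-bond donor and acceptor counts via rdkit."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return {
        "mw": float(Descriptors.MolWt(mol)),
        "logp": float(Crippen.MolLogP(mol)),
        "donors": float(RDLipinski.NumHDonors(mol)),
        "acceptors": float(RDLipinski.NumHAcceptors(mol)),
    }


def _as_records(molecules) -> list[SmilesRecord]:
    if isinstance(molecules, str):
        return list(iter_smiles_records(molecules))
    out = []
    for i, m in enumerate(molecules):
        if isinstance(m, SmilesRecord):
            out.append(m)
        elif isinstance(m, MoleculeGraph):
            out.append(SmilesRecord(smiles="", mol_id=f"mol{i:06d}", graph=m))
        elif isinstance(m, str):
            from .ligand import parse_smiles
            out.append(parse_smiles(m))
        else:
            raise TypeError(f"unsupported library entry {type(m)!r}")
    return out


def screen(network, pocket: PocketGrid, molecules, batch_size: int = 256,
           discard_oversized: bool = False,
           compute_properties: bool = True) -> list[ScreeningRecord]:
    """Predict and rank a molecule library against one pocket.

    ``molecules`` may be SMILES-file text, an iterable of SMILES lines /
    :class:`SmilesRecord` / :class:`MoleculeGraph`. Unparseable entries
    keep a flagged, unranked record. Oversized molecules are pruned to 36
    heavy atoms by default (``discard_oversized`` flags them out
    instead). Records come back sorted by predicted pK descending with
    ties stable in input order.
    """
    network_obj = getattr(network, "network", network)  # accept Results
    parsed = _as_records(molecules)
    if not parsed:
        raise ValueError("empty molecule library")

    records: list[ScreeningRecord] = []
    encodable: list[int] = []
    feats = []
    for i, rec in enumerate(parsed):
        sr = ScreeningRecord(rec.mol_id or f"mol{i:06d}", rec.smiles)
        if rec.graph is None:
            sr.flags.append(rec.error or "parse failure")
            records.append(sr)
            continue
        graph = rec.graph
        if graph.n_atoms > MAX_ATOMS:
            if discard_oversized:
                sr.flags.append(f"discarded: {graph.n_atoms} heavy atoms")
                records.append(sr)
                continue
            graph = prune_ligand(graph)
            sr.flags.append("pruned")
        if compute_properties and rec.smiles:
            props = molecule_properties(rec.smiles)
            if props is not None:
                if rec.logp is not None:
                    props["logp"] = rec.logp
                    sr.logp_source = "library"
                else:
                    sr.logp_source = "computed"
                count, missing = lipinski_violations(
                    props["mw"], props["logp"],
                    props["donors"], props["acceptors"])
                sr.lipinski_violations = count
                for name in missing:
                    sr.flags.append(f"{name} not evaluable")
        feats.append(encode_ligand(graph).flatten())
        encodable.append(len(records))
        records.append(sr)

    if encodable:
        xl = np.stack(feats)
        # duplicated molecules share one prediction row: identical inputs
        # must give bit-identical outputs regardless of batch position
        keys: dict[bytes, int] = {}
        row_of = np.empty(xl.shape[0], dtype=int)
        for i in range(xl.shape[0]):
            row_of[i] = keys.setdefault(xl[i].tobytes(), len(keys))
        unique = xl[np.sort(np.unique(row_of, return_index=True)[1])] \
            if len(keys) < xl.shape[0] else xl
        xp = np.repeat(pocket.flatten()[None, :], unique.shape[0], axis=0)
        preds = predict_batch(network_obj, xp, unique,
                              batch_size=batch_size)[row_of]
        e_col = tg.DEFAULT_TERM_NAMES.index(tg.REQUIRED_TERM) * tg.N_STATS \
            + tg.STAT_NAMES.index("min")
        for row, idx in enumerate(encodable):
            records[idx].pred_pk = float(preds[row, -1])
            records[idx].pred_min_e = float(preds[row, e_col])

    ranked = sorted((r for r in records if r.ok),
                    key=lambda r: -r.pred_pk)  # stable: ties keep input order
    for rank, rec in enumerate(ranked):
        rec.rank = rank
    failed = [r for r in records if not r.ok]
    return ranked + failed


def top_k(records: list[ScreeningRecord], k: int) -> list[ScreeningRecord]:
    """First min(k, n) ranked records (failures never included)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [r for r in records if r.ok][:k]


def records_to_tsv(records: list[ScreeningRecord]) -> str:
    """Serialize screening records as the ranked TSV."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in records:
        lines.append("\t".join([
            "" if r.rank is None else str(r.rank),
            r.mol_id,
            r.smiles,
            "" if r.pred_pk is None else f"{r.pred_pk:.6g}",
            "" if r.pred_min_e is None else f"{r.pred_min_e:.6g}",
            "" if r.lipinski_violations is None
            else str(r.lipinski_violations),
            ";".join(r.flags),
        ]))
    return "\n".join(lines) + "\n"
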