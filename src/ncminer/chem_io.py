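"""Compound / interaction table I/O, fingerprinting, and raw structural similarity.

Interaction tables follow the common chemogenomics layout: one row per
(compound, protein) pair with an activity flag, ``'A'`` for active and
``'N'`` for inactive.  Compounds are described either by a SMILES string
(fingerprinted here via RDKit) or directly by a pre-built binary
fingerprint (hex-packed in a ``fingerprint_hex`` column), which is how the
synthetic generator emits data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import DataStructs

from .errors import (
    ConfigurationError,
    DimensionError,
    EmptyDatasetError,
    FingerprintError,
)

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter is reported via our own counters

REQUIRED_COLUMNS = ("compound_id", "protein_id", "activity")
ACTIVITY_MAP = {"A": True, "N": False}


# ---------------------------------------------------------------------------
# fingerprint spec & computation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintSpec:
    """Descriptor of the fingerprint dialect a dataset / model uses.

    Stored inside every dataset and checkpoint so train/predict dialect
    mismatches are detectable and rejected rather than silently scored.
    """

    name: str = "rdkit-path"
    n_bits: int = 1024
    params: tuple = ()

    def to_dict(self) -> dict:
        return {"name": self.name, "n_bits": self.n_bits, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintSpec":
        return cls(d["name"], int(d["n_bits"]), tuple(d.get("params", ())))

    @classmethod
    def synthetic(cls, n_bits: int = 1024) -> "FingerprintSpec":
        return cls(name="synthetic-bits", n_bits=n_bits)


def compute_fingerprint(
    smiles: str,
    spec: FingerprintSpec | None = None,
    standardize: bool = False,
) -> np.ndarray:
    """Path-based binary fingerprint of ``spec.n_bits`` bits from a SMILES string.

    Deterministic and canonicalization-invariant: two SMILES of the same
    molecule yield identical vectors.  ``standardize=True`` keeps only the
    largest covalent fragment (salt stripping) before fingerprinting.

    Raises
    ------
    FingerprintError
        If the SMILES does not parse.
    """
    spec = spec or FingerprintSpec()
    if spec.name != "rdkit-path":
        raise ConfigurationError(
            f"cannot compute {spec.name!r} fingerprints from SMILES"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(smiles)
    if standardize:
        frags = Chem.GetMolFrags(mol, asMols=True)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    bv = Chem.RDKFingerprint(mol, fpSize=spec.n_bits)
    arr = np.zeros(spec.n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return arr


def fp_to_hex(fp: np.ndarray) -> str:
    """Pack a 0/1 vector into a hex string (MSB-first per byte)."""
    return np.packbits(np.asarray(fp, dtype=np.uint8)).tobytes().hex()


def hex_to_fp(hexstr: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    bits = np.unpackbits(raw)[:n_bits]
    if bits.size < n_bits:
        raise DimensionError(f"hex fingerprint shorter than {n_bits} bits")
    return bits.astype(np.uint8)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two bit vectors.

    Convention: two all-zero vectors are defined as similarity 1.0 (identical),
    with a warning — degenerate inputs must not crash the pipeline.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; returning 1.0")
        return 1.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(compounds: "list[CompoundRecord] | np.ndarray") -> np.ndarray:
    """Pairwise Tanimoto similarity matrix (symmetric, unit diagonal).

    Accepts a list of :class:`CompoundRecord` or a (n, n_bits) 0/1 array.
    Computed via bit-count algebra rather than a double loop.
    """
    if len(compounds) == 0:
        raise EmptyDatasetError("tanimoto_matrix needs at least one compound")
    if isinstance(compounds[0], CompoundRecord):
        fps = np.stack([c.fingerprint for c in compounds])
    else:
        fps = np.asarray(compounds)
    fps = fps.astype(np.float64)
    inter = fps @ fps.T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def plot_tanimoto_heatmap(matrix: np.ndarray, path: str | Path) -> None:
    """Optional heat-map export of a similarity matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, vmin=0.0, vmax=1.0, cmap="viridis")
    fig.colorbar(im, ax=ax, label="Tanimoto similarity")
    ax.set_xlabel("compound index")
    ax.set_ylabel("compound index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class CompoundRecord:
    """A compound: opaque id, optional SMILES, and a binary fingerprint."""

    compound_id: str
    fingerprint: np.ndarray
    smiles: str | None = None

    def __post_init__(self):
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        if not np.isin(self.fingerprint, (0, 1)).all():
            raise ConfigurationError(
                f"fingerprint of {self.compound_id!r} contains non-binary values"
            )


@dataclass
class InteractionDataset:
    """Compounds plus (compound, protein, active?) records with per-protein views.

    ``interactions`` is a DataFrame with columns ``compound_id``,
    ``protein_id`` and boolean ``active``; (compound_id, protein_id) is unique.
    """

    compounds: dict[str, CompoundRecord]
    interactions: pd.DataFrame
    fingerprint_spec: FingerprintSpec
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS[:2] if c not in self.interactions.columns]
        if missing or "active" not in self.interactions.columns:
            raise ConfigurationError("interactions must have compound_id/protein_id/active")
        unknown = set(self.interactions["compound_id"]) - set(self.compounds)
        if unknown:
            raise ConfigurationError(
                f"{len(unknown)} interaction compound ids lack compound records "
                f"(e.g. {sorted(unknown)[:3]})"
            )
        dup = self.interactions.duplicated(subset=["compound_id", "protein_id"])
        if dup.any():
            raise ConfigurationError("duplicate (compound, protein) interaction rows")
        n = self.fingerprint_spec.n_bits
        for cid, rec in self.compounds.items():
            if rec.fingerprint.size != n:
                raise DimensionError(
                    f"compound {cid!r} fingerprint length {rec.fingerprint.size} != spec {n}"
                )

    # -- views ------------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.interactions["protein_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return list(self.compounds)

    def actives_of(self, protein_id: str) -> list[str]:
        m = (self.interactions["protein_id"] == protein_id) & self.interactions["active"]
        return self.interactions.loc[m, "compound_id"].tolist()

    def inactives_of(self, protein_id: str) -> list[str]:
        m = (self.interactions["protein_id"] == protein_id) & ~self.interactions["active"]
        return self.interactions.loc[m, "compound_id"].tolist()

    def active_proteins_of(self, compound_id: str) -> set[str]:
        m = (self.interactions["compound_id"] == compound_id) & self.interactions["active"]
        return set(self.interactions.loc[m, "protein_id"])

    def fingerprint_matrix(self, compound_ids: list[str] | None = None) -> np.ndarray:
        ids = compound_ids if compound_ids is not None else self.compound_ids
        return np.stack([self.compounds[c].fingerprint for c in ids])

    def subset(self, compound_ids) -> "InteractionDataset":
        """View restricted to the given compounds (interactions filtered to match)."""
        keep = set(compound_ids)
        inter = self.interactions[self.interactions["compound_id"].isin(keep)]
        return InteractionDataset(
            compounds={c: self.compounds[c] for c in compound_ids},
            interactions=inter.reset_index(drop=True),
            fingerprint_spec=self.fingerprint_spec,
        )

    def __len__(self) -> int:
        return len(self.compounds)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read a ``.smi``-style two-column file (SMILES, id) into id -> SMILES."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ConfigurationError(f"SMILES file line needs 'SMILES id': {line!r}")
        out[parts[1]] = parts[0]
    return out


def read_interactions(
    path: str | Path,
    fingerprint_spec: FingerprintSpec | None = None,
    smiles_table: dict[str, str] | None = None,
    dedupe: str = "first",
    standardize: bool = False,
) -> InteractionDataset:
    """Read a CSV/TSV interaction table into a validated :class:`InteractionDataset`.

    The table needs header columns ``compound_id, protein_id, activity``
    (activity in {A, N}) and either a ``smiles`` or ``fingerprint_hex`` column;
    alternatively pass ``smiles_table`` (id -> SMILES, e.g. from
    :func:`read_smiles_file`) alongside a structure-less table.  Rows whose
    SMILES fail to parse are dropped and counted in ``dataset.report``.

    ``dedupe``: "first" keeps the first of duplicated (compound, protein)
    rows; "error" raises instead.
    """
    path = Path(path)
    spec = fingerprint_spec
    if spec is None:
        sidecar = Path(str(path) + ".spec.json")
        if sidecar.exists():
            spec = FingerprintSpec.from_dict(json.loads(sidecar.read_text()))
        else:
            spec = FingerprintSpec()
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: missing required columns {missing}")
    has_structure = "smiles" in df.columns or "fingerprint_hex" in df.columns
    if not has_structure and smiles_table is None:
        raise ConfigurationError(
            f"{path.name}: needs a 'smiles' or 'fingerprint_hex' column, "
            "or a separate SMILES table"
        )

    bad_activity = ~df["activity"].isin(ACTIVITY_MAP)
    if bad_activity.any():
        raise ConfigurationError(
            f"{path.name}: activity flags must be 'A' or 'N'; got "
            f"{sorted(df.loc[bad_activity, 'activity'].unique())}"
        )

    n_dup = int(df.duplicated(subset=["compound_id", "protein_id"]).sum())
    if n_dup:
        if dedupe == "error":
            raise ConfigurationError(
                f"{path.name}: {n_dup} duplicated (compound, protein) rows"
            )
        df = df.drop_duplicates(subset=["compound_id", "protein_id"], keep="first")

    compounds: dict[str, CompoundRecord] = {}
    n_dropped = 0
    dropped_ids: list[str] = []
    for cid, grp in df.groupby("compound_id", sort=False):
        row = grp.iloc[0]
        smiles = None
        try:
            if "fingerprint_hex" in df.columns and pd.notna(row.get("fingerprint_hex")):
                fp = hex_to_fp(row["fingerprint_hex"], spec.n_bits)
            else:
                smiles = (
                    smiles_table[cid] if smiles_table is not None else row["smiles"]
                )
                fp = compute_fingerprint(smiles, spec, standardize=standardize)
        except (FingerprintError, KeyError, DimensionError):
            n_dropped += 1
            dropped_ids.append(str(cid))
            continue
        compounds[str(cid)] = CompoundRecord(str(cid), fp, smiles=smiles)

    df = df[df["compound_id"].isin(compounds)].copy()
    if df.empty:
        raise EmptyDatasetError(f"{path.name}: no valid interaction rows")
    df["active"] = df["activity"].map(ACTIVITY_MAP)
    inter = df[["compound_id", "protein_id", "active"]].reset_index(drop=True)
    return InteractionDataset(
        compounds=compounds,
        interactions=inter,
        fingerprint_spec=spec,
        report={
            "n_rows": int(len(inter)),
            "n_compounds": len(compounds),
            "n_dropped_compounds": n_dropped,
            "dropped_compound_ids": dropped_ids,
            "n_deduplicated_rows": n_dup,
        },
    )


def write_interactions(ds: InteractionDataset, path: str | Path) -> None:
    """Serialize a dataset back to CSV (round-trips through read_interactions)."""
    path = Path(path)
    rows = []
    for _, r in ds.interactions.iterrows():
        rec = ds.compounds[r["compound_id"]]
        rows.append(
            {
                "compound_id": rec.compound_id,
                "smiles": rec.smiles if rec.smiles is not None else "",
                "fingerprint_hex": fp_to_hex(rec.fingerprint),
                "protein_id": r["protein_id"],
                "activity": "A" if r["active"] else "N",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sniff_sep(path), index=False)
    Path(str(path) + ".spec.json").write_text(
        json.dumps(ds.fingerprint_spec.to_dict(), indent=1)
    )


def write_fingerprint_matrix(ds: InteractionDataset, path: str | Path) -> None:
    """Dense 0/1 matrix as whitespace text plus a JSON sidecar with the spec."""
    path = Path(path)
    mat = ds.fingerprint_matrix()
    np.savetxt(path, mat, fmt="%d")
    sidecar = {
        "fingerprint_spec": ds.fingerprint_spec.to_dict(),
        "compound_ids": ds.compound_ids,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
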