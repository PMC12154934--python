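"""Packaged fixtures and synthetic data generators.

Fixtures
--------
Three plain-TSV fixtures ship with the package:

* a 34-protein test manifest (PDB id, chain, length; lengths 30-44),
* the 20-row amino-acid property table (hydrophobicity, molecular mass,
  van der Waals volume, dipole moment, aromaticity, acidity/basicity),
* reference p-value tables for the three protein language models
  (ProtBERT, ProtT5, Ankh) x nine attribution methods x two modes x two
  roles x seven properties -- 324 categorical (Mann-Whitney) rows and 432
  numerical (Kendall) rows, stored exactly as printed (mantissa/exponent
  text) alongside a parsed float so significance thresholding never
  suffers re-rounding.

Synthetic data
--------------
Random protein sequences over the 20 canonical letters with i.i.d.
Bernoulli interaction labels, and Gaussian random matrices used as the
null ensemble in the real-vs-random separability check.  All generators
are bit-reproducible under a fixed seed.

Everywhere a 20-vector indexed by amino acid appears, the letters are in
alphabetical order (``AA_ALPHABET``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AROMATIC = frozenset("FYW")
ACIDIC = frozenset("DE")
BASIC = frozenset("HKR")

CATEGORICAL_PROPERTIES = ("interactivity", "aromaticity", "acidity_basicity")
NUMERICAL_PROPERTIES = ("hydrophobicity", "molecular_mass", "vdw_volume", "dipole_moment")

MODELS = ("ProtBERT", "ProtT5", "Ankh")
XAI_METHODS = (
    "saliency",
    "deconvolution",
    "guided_backprop",
    "input_x_gradient",
    "deeplift",
    "integrated_gradients",
    "lime",
    "kernelshap",
    "gradientshap",
)
MODES = ("embedding", "prediction")
ROLES = ("target", "source")


class FixtureFormatError(ValueError):
    """A packaged fixture is malformed (names the offending row)."""


def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("protattr") / "data" / name)


@dataclass
class ProteinRecord:
    """One protein chain: sequence and optional per-residue interaction labels.

    ``interaction_labels`` is a 0/1 vector, 1 marking residues observed (or
    planted) to bind other proteins.  Manifest entries carry no labels or
    sequence (only the declared length); synthetic records carry both.
    """

    protein_id: str
    chain_id: str
    length: int
    sequence: str | None = None
    interaction_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: non-positive length {self.length}")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.protein_id}: sequence length {len(self.sequence)} != {self.length}"
                )
            bad = set(self.sequence) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"{self.protein_id}: non-canonical residues {sorted(bad)}")
        if self.interaction_labels is not None:
            self.interaction_labels = np.asarray(self.interaction_labels, dtype=np.int8)
            if self.interaction_labels.shape != (self.length,):
                raise ValueError(f"{self.protein_id}: label vector shape mismatch")
            if not np.isin(self.interaction_labels, (0, 1)).all():
                raise ValueError(f"{self.protein_id}: labels must be 0/1")

    @property
    def name(self) -> str:
        return f"{self.protein_id}_{self.chain_id}"


def load_protein_manifest() -> list[ProteinRecord]:
    """Load the packaged 34-chain test manifest (no sequences or labels)."""
    records = []
    path = _fixture_path("protein_manifest.tsv")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["protein_id", "chain_id", "length"]:
            raise FixtureFormatError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or not parts[2].isdigit():
                raise FixtureFormatError(f"{path}:{lineno}: malformed row {line!r}")
            records.append(ProteinRecord(parts[0], parts[1], int(parts[2])))
    if len(records) != 34:
        raise FixtureFormatError(f"{path}: expected 34 records, found {len(records)}")
    return records


def load_property_table() -> pd.DataFrame:
    """Load the amino-acid property table, indexed by letter (alphabetical).

    Columns: ``hydrophobicity`` (Kyte-Doolittle-style, dimensionless),
    ``molecular_mass`` (Da, residue mass), ``vdw_volume`` (A^3),
    ``dipole_moment`` (dimensionless as tabulated), ``aromatic`` (bool),
    ``acid_base`` (``acidic`` / ``basic`` / ``neither``).
    """
    path = _fixture_path("amino_acid_properties.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"letter": str})
    expected = ["letter", "hydrophobicity", "molecular_mass", "vdw_volume",
                "dipole_moment", "aromatic", "acid_base"]
    if list(df.columns) != expected:
        raise FixtureFormatError(f"{path}: unexpected columns {list(df.columns)}")
    df["aromatic"] = df["aromatic"].map({"true": True, "false": False, True: True, False: False})
    df = df.set_index("letter").sort_index()
    missing = set(AA_ALPHABET) - set(df.index)
    if missing:
        raise FixtureFormatError(f"{path}: missing amino acids {sorted(missing)}")
    if len(df) != 20:
        raise FixtureFormatError(f"{path}: expected 20 rows, found {len(df)}")
    if set(df.index[df["aromatic"]]) != AROMATIC:
        raise FixtureFormatError(f"{path}: aromatic set is not {{F,Y,W}}")
    if set(df.index[df["acid_base"] == "acidic"]) != ACIDIC:
        raise FixtureFormatError(f"{path}: acidic set is not {{D,E}}")
    if set(df.index[df["acid_base"] == "basic"]) != BASIC:
        raise FixtureFormatError(f"{path}: basic set is not {{H,K,R}}")
    return df


@dataclass
class ReportedPValueTable:
    """The packaged reference statistical-test tables.

    ``categorical``: 324 Mann-Whitney rows (model, xai_method, mode, role,
    property, p_printed, p_value).  ``numerical``: 432 Kendall rows with an
    additional signed correlation ``tau``.
    """

    categorical: pd.DataFrame
    numerical: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        """Tidy concatenation with a ``kind`` column; 756 rows."""
        cat = self.categorical.assign(kind="categorical", tau=np.nan)
        num = self.numerical.assign(kind="numerical")
        cols = ["model", "xai_method", "mode", "role", "property", "tau",
                "p_printed", "p_value", "kind"]
        return pd.concat([cat[cols], num[cols]], ignore_index=True)


def load_reported_pvalues() -> ReportedPValueTable:
    """Load the 756-row reference p-value fixture (324 categorical + 432 numerical)."""
    cat = pd.read_csv(_fixture_path("reported_pvalues_categorical.tsv"), sep="\t")
    num = pd.read_csv(_fixture_path("reported_pvalues_numerical.tsv"), sep="\t")
    if len(cat) != 324:
        raise FixtureFormatError(f"categorical fixture: expected 324 rows, found {len(cat)}")
    if len(num) != 432:
        raise FixtureFormatError(f"numerical fixture: expected 432 rows, found {len(num)}")
    for df, props in ((cat, CATEGORICAL_PROPERTIES), (num, NUMERICAL_PROPERTIES)):
        keys = df[["model", "xai_method", "mode", "role", "property"]]
        if keys.duplicated().any():
            raise FixtureFormatError("duplicate (model, method, mode, role, property) rows")
        if set(df["property"]) != set(props):
            raise FixtureFormatError(f"unexpected property names {set(df['property'])}")
        if not df["p_value"].between(0, 1).all():
            raise FixtureFormatError("p-values outside [0, 1]")
    if not num["tau"].between(-1, 1).all():
        raise FixtureFormatError("correlations outside [-1, 1]")
    return ReportedPValueTable(categorical=cat, numerical=num)


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

def generate_synthetic_proteins(
    count: int,
    length_range: tuple[int, int],
    interaction_rate: float,
    seed: int,
    composition_bias: dict[str, float] | None = None,
) -> list[ProteinRecord]:
    """Generate random protein records with planted Bernoulli interaction labels.

    Residues are drawn uniformly over the 20 canonical letters unless
    ``composition_bias`` maps letters to relative weights.  Lengths are
    uniform over the closed interval ``length_range`` (within [5, 44], the
    regime the analysis targets).  Reproducible given ``seed``.
    """
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"empty length interval {length_range}")
    if not (5 <= lo and hi <= 44):
        raise ValueError(f"length_range {length_range} outside [5, 44]")
    if not (0.0 < interaction_rate < 1.0):
        raise ValueError(f"interaction_rate must lie in (0, 1), got {interaction_rate}")
    if count <= 0:
        raise ValueError(f"count must be positive, got {count}")
    weights = np.ones(20)
    if composition_bias:
        for letter, wgt in composition_bias.items():
            if letter not in AA_ALPHABET:
                raise ValueError(f"unknown amino-acid letter {letter!r}")
            weights[AA_ALPHABET.index(letter)] = wgt
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(count):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_ALPHABET[k] for k in rng.choice(20, size=n, p=probs))
        labels = (rng.random(n) < interaction_rate).astype(np.int8)
        records.append(ProteinRecord(f"SYN{i:04d}", "A", n, seq, labels))
    return records


def generate_random_matrix(
    n_rows: int, n_cols: int, mean: float, std: float, seed: int
) -> np.ndarray:
    """I.i.d. Gaussian matrix, the null ensemble for the separability check."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError(f"non-positive dimensions ({n_rows}, {n_cols})")
    if std <= 0:
        raise ValueError(f"std must be positive, got {std}")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, std, size=(n_rows, n_cols))


# ---------------------------------------------------------------------------
# FASTA + label-file round trip
# ---------------------------------------------------------------------------

def write_fasta_with_labels(
    records: list[ProteinRecord], fasta_path: str | Path, label_path: str | Path | None = None
) -> None:
    """Write sequences as FASTA and labels as a companion 0/1-string file.

    The label file follows the DELPHI-style convention: for each record a
    header line ``>id_chain`` followed by a same-length string of 0/1
    characters.  Records without labels are written with ``-`` placeholders.
    """
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.name, description="")
        for r in records
        if r.sequence is not None
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if label_path is not None:
        with open(label_path, "w") as fh:
            for r in records:
                if r.sequence is None:
                    continue
                if r.interaction_labels is None:
                    lab = "-" * r.length
                else:
                    lab = "".join(str(int(v)) for v in r.interaction_labels)
                fh.write(f">{r.name}\n{lab}\n")


def read_fasta_with_labels(
    fasta_path: str | Path, label_path: str | Path | None = None
) -> list[ProteinRecord]:
    """Read FASTA (+ optional companion label file) back into records."""
    labels: dict[str, np.ndarray] = {}
    if label_path is not None:
        with open(label_path) as fh:
            name = None
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    name = line[1:]
                elif name is not None and line and "-" not in line:
                    labels[name] = np.array([int(c) for c in line], dtype=np.int8)
    records = []
    for seq in SeqIO.parse(str(fasta_path), "fasta"):
        pid, _, chain = seq.id.rpartition("_")
        records.append(
            ProteinRecord(
                pid or seq.id,
                chain if pid else "A",
                len(seq.seq),
                str(seq.seq),
                labels.get(seq.id),
            )
        )
    return records
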