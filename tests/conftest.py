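from __future__ import annotations

import pytest

from famtrend.sequence_io import AlignedFamily


@pytest.fixture
def tiny_family() -> AlignedFamily:
    return AlignedFamily(
        ids=["s1", "s2", "s3", "s4"],
        rows=[
            "--ACDE-FG-",
            "MKACDE-FGH",
            "MKACNE-FG-",
            "--ACDEWFG-",
        ],
    )


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def format_pdb(residues) -> str:
    """Build PDB text. residues: (record, resname, chain, resseq, icode,
    [(atom_name, element, (x, y, z)), ...]) tuples."""
    lines = []
    serial = 1
    for record, resname, chain, resseq, icode, atoms in residues:
        for name, element, (x, y, z) in atoms:
            lines.append(
                f"{record:<6}{serial:>5} {name:^4} {resname:<3} {chain}"
                f"{resseq:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {element:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def simple_chain_pdb(seq3: list[str], chain: str = "A", start: int = 1) -> str:
    """One CA atom per residue, spaced 3.8 Å along x."""
    residues = []
    for i, resname in enumerate(seq3):
        residues.append(
            ("ATOM", resname, chain, start + i, " ",
             [("CA", "C", (3.8 * i, 0.0, 0.0))])
        )
    return format_pdb(residues)


@pytest.fixture
def write_pdb(tmp_path):
    def _write(text: str, name: str = "toy.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
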