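import numpy as np
import pytest

from dtilearn.pssm import DEFAULT_ALPHABET


def make_pssm_text(scores, residues=None, forty_column: bool = False,
                   crlf: bool = False) -> str:
    """Render a score matrix as PSI-BLAST -out_ascii_pssm text."""
    scores = np.asarray(scores)
    n = scores.shape[0]
    residues = residues or ("A" * n)
    letters = "  ".join(DEFAULT_ALPHABET)
    header = f"            {letters}  {letters}" if forty_column else f"            {letters}"
    lines = [
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "",
        header,
    ]
    for i, row in enumerate(scores):
        cells = " ".join(f"{int(v):3d}" for v in row)
        extra = ""
        if forty_column:
            extra = " " + " ".join(f"{int(abs(v)) % 100:3d}" for v in row)
        lines.append(f"{i + 1:5d} {residues[i]}  {cells}{extra}  0.36 0.08")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1367     0.3210",
        "",
    ]
    text = "\n".join(lines)
    return text.replace("\n", "\r\n") if crlf else text


@pytest.fixture
def pssm_text_3rows():
    """3-residue fixture with row i = constant i (i = 0, 1, 2)."""
    scores = np.array([[i] * 20 for i in range(3)])
    return make_pssm_text(scores, residues="MKL")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
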