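import numpy as np
import pytest

from circfold import (
    default_params,
    fixtures,
    map_to_cg,
    parse_dotbracket,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def helix_chain():
    """Single-strand ideal helix containing all four bases (energy minimum)."""
    return map_to_cg(fixtures.build_single_helix("ACGUACGU"))


@pytest.fixture(scope="session")
def hairpin():
    """12-nt stem-loop: (sequence, dot-bracket, CGChain, PairTable)."""
    seq, db, structure = fixtures.build_hairpin(4, 4)
    chain = map_to_cg(structure)
    pt = parse_dotbracket(seq, db, circular=False)
    return seq, db, chain, pt


@pytest.fixture(scope="session")
def open_hairpin():
    seq, db, structure = fixtures.build_open_hairpin()
    chain = map_to_cg(structure)
    pt = parse_dotbracket(seq, db, circular=False)
    return seq, db, chain, pt


def quaternion_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Independent minimum-RMSD oracle via Horn's quaternion method.

    The optimal superposition RMSD follows from the largest eigenvalue of
    the 4x4 key matrix built from the covariance of the centered point sets.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = yc.T @ xc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
        [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
        [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
        [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    gsq = float((xc * xc).sum() + (yc * yc).sum())
    msd = max(0.0, (gsq - 2.0 * lam) / n)
    return float(np.sqrt(msd))
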