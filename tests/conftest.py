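import numpy as np
import pandas as pd
import pytest

from npscreen.gsea import RankedList


@pytest.fixture
def write_tsv(tmp_path):
    """Write a DataFrame (or list of dicts) to a TSV file and return the path."""
    def _write(data, name="table.tsv"):
        df = data if isinstance(data, pd.DataFrame) else pd.DataFrame(data)
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path
    return _write


@pytest.fixture
def sumstats_rows():
    """Three valid summary-statistics rows in the canonical dialect."""
    return pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "2"],
        "POS": [1000, 2000, 3000],
        "EA": ["A", "C", "G"],
        "OA": ["G", "T", "A"],
        "EAF": [0.2, 0.4, 0.1],
        "BETA": [0.1, -0.2, 0.05],
        "SE": [0.02, 0.04, 0.01],
        "P": [1e-6, 1e-4, 1e-3],
    })


def brute_force_es(stats: np.ndarray, member_idx: set, q: float,
                   score_type: str = "pos") -> float:
    """Direct O(N) running-sum enrichment score (independent oracle)."""
    n = len(stats)
    w = np.abs(stats) ** q
    tot = sum(w[i] for i in member_idx)
    n_miss = n - len(member_idx)
    p_hit = p_miss = 0.0
    best, worst = -np.inf, np.inf
    for i in range(n):
        if i in member_idx:
            p_hit += (w[i] / tot) if tot > 0 else 1.0 / len(member_idx)
        else:
            p_miss += 1.0 / n_miss
        dev = p_hit - p_miss
        best = max(best, dev)
        worst = min(worst, dev)
    if score_type == "pos":
        return best
    return best if best >= -worst else worst


@pytest.fixture
def ranked_abc():
    return RankedList.from_stats(["a", "b", "c"], [3.0, 2.0, 1.0])
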