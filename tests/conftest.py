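import numpy as np
import pandas as pd
import pytest

from comotif.motifs import PWM


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pwm(rng, width=None, motif_id="M", tf_name="tf"):
    """A random informative PWM (Dirichlet columns, one peaked base)."""
    width = width or int(rng.integers(3, 10))
    mat = rng.dirichlet([0.6, 0.6, 0.6, 0.6], size=width)
    return PWM(motif_id, tf_name, mat)


def sharp_pwm(consensus: str, motif_id="M", tf_name="tf", dominant=0.94):
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(consensus), 4), (1 - dominant) / 3)
    for j, b in enumerate(consensus):
        mat[j, code[b]] = dominant
    return PWM(motif_id, tf_name, mat)


def sites_frame(rows):
    """Build a site table from (motif_id, chrom, start, end[, percentile]) tuples."""
    cols = ["motif_id", "chrom", "start", "end", "percentile"]
    recs = [list(r) + [1.0] * (5 - len(r)) for r in rows]
    df = pd.DataFrame(recs, columns=cols)
    df["strand"] = "+"
    df["score"] = 1.0
    df["pvalue"] = 1e-5
    return df
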