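import numpy as np
import pandas as pd
import pytest

from polyribo.pipeline import analyze
from polyribo.simulate import SimulationConfig, simulate_experiment
from polyribo.transcripts import CODING, NONCODING, Transcript


def make_coding(tid="tx1", utr5=30, cds_aa=19, utr3=30, seed=0, gene=None):
    """A valid coding transcript with a clean ATG..stop CDS."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    sense = [a + b + c for a in bases for b in bases for c in bases
             if a + b + c not in ("TAA", "TAG", "TGA")]
    cds = "ATG" + "".join(sense[i] for i in rng.integers(0, len(sense), cds_aa - 1)) + "TAA"
    u5 = "".join(bases[i] for i in rng.integers(0, 4, utr5))
    u3 = "".join(bases[i] for i in rng.integers(0, 4, utr3))
    seq = u5 + cds + u3
    return Transcript(tid, gene or f"g_{tid}", CODING, seq,
                      (0, utr5), (utr5, utr5 + len(cds)), (utr5 + len(cds), len(seq)))


def make_noncoding(tid="nc1", sequence="A" * 100):
    return Transcript(tid, f"g_{tid}", NONCODING, sequence, (0, 0), (0, 0), (0, 0))


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


@pytest.fixture(scope="session")
def default_sim():
    """One full simulated experiment at the standard study conditions."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_sim):
    """Full analysis of the default simulation (thresholds derived from background)."""
    sim = default_sim
    return analyze(sim.transcripts, sim.footprints, sim.mrna, seed=1001)


def reads_frame(rows):
    """Alignment DataFrame from (transcript_id, start, length[, multiplicity]) tuples."""
    norm = [(r[0], r[1], r[2], r[3] if len(r) > 3 else 1) for r in rows]
    return pd.DataFrame(norm, columns=["transcript_id", "start", "length", "multiplicity"])
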