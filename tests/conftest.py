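import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from multisv.core import Breakend, CallSet, Provenance, SVRecord
from multisv.simulate import GenomeModel, emulate_callsets, simulate_truth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(rid, svtype, chrom, pos, size=0, chrom2=None, pos2=None, **kw):
    """Shorthand SVRecord constructor for tests."""
    if svtype == "INS":
        b = Breakend(chrom, pos)
        return SVRecord(rid, "INS", b, b, size=size, **kw)
    if svtype in ("TRA", "BND"):
        return SVRecord(rid, svtype, Breakend(chrom, pos),
                        Breakend(chrom2 or chrom, pos2), **kw)
    return SVRecord(rid, svtype, Breakend(chrom, pos),
                    Breakend(chrom, pos + size), **kw)


def random_records(rng, n, chroms=("chr1", "chr2"), span=200_000,
                   types=("DEL", "DUP", "INS", "INV", "TRA")):
    """Random SVs concentrated enough that merge links actually occur."""
    loci = [
        (chroms[int(rng.integers(len(chroms)))], int(rng.integers(10_000, span)))
        for _ in range(max(2, n // 4))
    ]
    out = []
    for k in range(n):
        svtype = types[int(rng.integers(len(types)))]
        chrom, base = loci[int(rng.integers(len(loci)))]
        pos = base + int(rng.integers(-800, 800))
        pos = max(pos, 1)
        if svtype == "TRA":
            other = chroms[0] if chrom != chroms[0] else chroms[-1]
            out.append(make_record(f"r{k}", "TRA", chrom, pos, chrom2=other,
                                   pos2=50_000 + int(rng.integers(-800, 800))))
        elif svtype == "INS":
            out.append(make_record(f"r{k}", "INS", chrom, pos,
                                   size=int(rng.integers(50, 2_000))))
        else:
            out.append(make_record(f"r{k}", svtype, chrom, pos,
                                   size=int(rng.integers(50, 2_000))))
    return out


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeModel.toy(seed=7)


@pytest.fixture(scope="session")
def small_truth(toy_genome):
    return simulate_truth(toy_genome, seed=11)


@pytest.fixture(scope="session")
def study(toy_genome, small_truth):
    """One emulated multi-platform study shared across tests."""
    callsets = emulate_callsets(small_truth, toy_genome, seed=13)
    return {"genome": toy_genome, "truth": small_truth, "callsets": callsets}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tumor_prov():
    return Provenance("Illumina", "Manta", "1", "tumor")
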