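import numpy as np
import pytest

from metaqtl.catalog import PopulationDescriptor, QTLRecord
from metaqtl.linkage import LinkageMap, MarkerLocus


def make_map(map_id, chrom_to_positions, weight=1.0, prefix="m"):
    """Build a LinkageMap from {chrom: {name: pos}} or {chrom: [pos...]}."""
    loci = []
    for chrom, spec in chrom_to_positions.items():
        if isinstance(spec, dict):
            items = spec.items()
        else:
            items = ((f"{prefix}{i}", p) for i, p in enumerate(spec))
        loci.extend(MarkerLocus(n, chrom, float(p)) for n, p in items)
    return LinkageMap(map_id, loci, weight=weight)


def make_record(qtl_id="q1", stress="drought", chromosome="1H", peak_cm=50.0,
                r2=0.2, pop_type="DH", n_lines=100, study_id="s1", **kw):
    pop = PopulationDescriptor(pop_type, n_lines, study_id)
    return QTLRecord(qtl_id=qtl_id, trait=kw.pop("trait", "yield"), stress=stress,
                     chromosome=chromosome, peak_cm=peak_cm, r2=r2,
                     population=pop, **kw)


@pytest.fixture
def simple_map():
    return make_map("simple", {"1H": {"a": 0.0, "b": 5.0, "c": 12.0, "d": 30.0}})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
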