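import numpy as np
import pytest

from mrmediate.gwas_io import AssociationRecord, SummaryTable
from mrmediate.instruments import HarmonizedDataset, HarmonizedPair


@pytest.fixture
def make_dataset():
    """Build a HarmonizedDataset from effect arrays (test scaffolding)."""

    def _make(bx, by, sy, sx=None, exposure_name="X", outcome_name="Y"):
        bx = np.asarray(bx, dtype=float)
        by = np.asarray(by, dtype=float)
        sy = np.asarray(sy, dtype=float)
        sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
        pairs = [
            HarmonizedPair(
                snp_id=f"rs{i + 1}",
                effect_allele="A",
                other_allele="G",
                beta_exposure=float(bx[i]),
                se_exposure=float(sx[i]),
                beta_outcome=float(by[i]),
                se_outcome=float(sy[i]),
                eaf_exposure=0.3,
                eaf_outcome=0.3,
            )
            for i in range(len(bx))
        ]
        return HarmonizedDataset(
            exposure_name=exposure_name, outcome_name=outcome_name, pairs=pairs
        )

    return _make


@pytest.fixture
def make_table():
    """Build a valid SummaryTable from keyword-record tuples."""

    def _make(rows, trait_name="trait", trait_type="quantitative"):
        records = [AssociationRecord(**row) for row in rows]
        table = SummaryTable(
            trait_name=trait_name, trait_type=trait_type, records=records
        )
        table.validate()
        return table

    return _make


def record(snp, beta, se, pvalue, ea="A", oa="G", eaf=0.3, n=10000):
    return {
        "snp_id": snp,
        "effect_allele": ea,
        "other_allele": oa,
        "beta": beta,
        "se": se,
        "pvalue": pvalue,
        "eaf": eaf,
        "n": n,
    }
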