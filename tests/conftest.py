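import pytest

from lnpscreen import (
    ScaffoldLayout,
    assemble_scaffolds,
    build_pool,
    enumerate_formulations,
    generate_barcode_set,
    load_primer_set,
)


@pytest.fixture(scope="session")
def primer_set():
    return load_primer_set()


@pytest.fixture(scope="session")
def layout():
    return ScaffoldLayout()


@pytest.fixture(scope="session")
def small_bset():
    return generate_barcode_set(n=10, length=8, min_hamming=3, seed=11)


@pytest.fixture(scope="session")
def screen(primer_set):
    """A 65-LNP screened library with scaffolds and a uniform pool.

    Mirrors the standard screen scale: 128 designed formulations, 65 passing
    QC, one naked control barcode, total dose 1.5 mg/kg.
    """
    from lnpscreen import apply_qc
    from lnpscreen.synthetic import simulate_qc_table

    bset = generate_barcode_set(n=129, length=8, min_hamming=3, seed=101)
    formulations = enumerate_formulations(barcode_ids=bset.ids[:128])
    qc = simulate_qc_table(formulations, seed=5, n_pass=65)
    passed, failed = apply_qc(formulations, qc)
    pool = build_pool(passed, control_barcode_id=bset.ids[128],
                      total_dose_mg_per_kg=1.5)
    scaffolds = assemble_scaffolds(bset, primer_set)
    return {
        "bset": bset,
        "formulations": formulations,
        "passed": passed,
        "failed": failed,
        "pool": pool,
        "scaffolds": scaffolds,
    }
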