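import numpy as np
import pandas as pd
import pytest

from dnbdev.dataset import ExpressionDataset


def make_dataset(values, gene_ids=None, ages=None, species="synthetic", **kw):
    """Small ExpressionDataset from a 2-D array; ages default to 0.1*i."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    ages = list(ages) if ages is not None else [0.1 * i for i in range(s)]
    sample_ids = [f"s{i}" for i in range(s)]
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "species": species, "age_years": ages}
    )
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionDataset(frame, meta, **kw)


@pytest.fixture
def toy_tsvs(tmp_path):
    """3-gene x 4-sample expression TSV plus matching metadata."""
    matrix = tmp_path / "matrix.tsv"
    meta = tmp_path / "meta.tsv"
    matrix.write_text(
        "gene_id\ts1\ts2\ts3\ts4\n"
        "gA\t1\t2\t3\t4\n"
        "gB\t4\t3\t2\t1\n"
        "gC\t2\t2\t2\t2\n"
    )
    meta.write_text(
        "sample_id\tspecies\tage_years\n"
        "s1\thuman\t0.1\n"
        "s2\thuman\t0.3\n"
        "s3\thuman\t0.2\n"
        "s4\thuman\t0.9\n"
    )
    return matrix, meta


def pearson_brute(x, y):
    """Definitional Pearson correlation; 0.0 if either series is constant."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / (sxx**0.5 * syy**0.5)


def ci_brute(values, group_rows):
    """Brute-force (SD_d, PCC_d, PCC_o, CI) by explicit pair loops."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    group = sorted(group_rows)
    others = [i for i in range(g) if i not in set(group)]
    sds = []
    for i in group:
        row = values[i]
        m = row.mean()
        sds.append((sum((v - m) ** 2 for v in row) / (n - 1)) ** 0.5)
    sd_d = sum(sds) / len(sds)
    if len(group) == 1:
        pcc_d = 1.0
    else:
        acc = []
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                acc.append(abs(pearson_brute(values[group[a]], values[group[b]])))
        pcc_d = sum(acc) / len(acc)
    acc = []
    for i in group:
        for j in others:
            acc.append(abs(pearson_brute(values[i], values[j])))
    pcc_o = sum(acc) / len(acc)
    ci = float("inf") if pcc_o == 0 else sd_d * pcc_d / pcc_o
    return sd_d, pcc_d, pcc_o, ci
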