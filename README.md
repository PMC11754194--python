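# faers-signals

Disproportionality signal mining for spontaneous adverse-event reports in
the FAERS quarterly ASCII format, built as a reusable, tested pipeline.

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) are the main post-marketing source for detecting adverse
drug reactions that pre-market trials miss. The analysis they support is
*disproportionality*: for a target drug and each MedDRA preferred term
(PT), count the 2×2 table of unique (report, PT) pairs

|                  | event of interest | other events | total |
|------------------|-------------------|--------------|-------|
| target drug      | a                 | b            | a+b   |
| all other drugs  | c                 | d            | c+d   |

and flag PTs whose reporting rate with the drug exceeds the background.
The package computes four standard statistics per PT and their signal
criteria:

- **ROR** = ad/bc, 95% CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d);
  signal when a ≥ 3 and the CI lower bound exceeds 1.
- **PRR** = a(c+d)/(c(a+b)) with the uncorrected χ²; signal when a ≥ 3,
  PRR ≥ 2 and χ² ≥ 4.
- **BCPNN IC** = log₂(a·n/((a+c)(a+b))); signal when IC025 > 0, with
  intensity grades (0,1.5] weak (+), (1.5,3] medium (++), >3 high (+++).
- **EBGM** = a·n/((a+c)(a+b)) (the unshrunk observed/expected ratio) with
  a 95% interval reusing the ROR's log-scale SE; signal when EBGM05 > 2.

Around the statistics sits the full workflow a pharmacovigilance analyst
needs: FAERS-style "$"-delimited table I/O, removal of FDA-deleted cases,
collapse of duplicate CASEIDs (latest FDA_DT, ties to the largest
PRIMARYID), keyword screening for the target drug restricted to
primary-suspect rows, time-to-onset analysis with explicit exclusion
rules, sex-imbalance RORs, age-stratified signal tables, descriptive
cohort tables, EBGM05 ranking, and SOC-level aggregation. A synthetic
FAERS-like generator with planted drug–event associations provides ground
truth for every stage, so the whole pipeline is testable without
downloading the real database.

## Worked example

A single 2×2 table from the command line — 721 pair counts for a PT with
the target drug, against a 1M-pair background:

```
$ faers-signals stats -a 721 -b 25000 -c 900 -d 1000000 --ic-method bate1998
{
  "ror": 32.044444444444444,
  "ror_ci95": [29.030957724351783, 35.3707386956699],
  "prr": 31.174219941336304,
  "chi2": 11710.017543486574,
  "ic": 4.150000206527288,
  "ic_ci95": [3.9857451365262104, 4.246233117692631],
  "ebgm": 17.75311409451121,
  "ebgm_ci95": [16.083596195492852, 19.595932167275773],
  "pass": {"ror": true, "prr": true, "bcpnn": true, "mgps": true, "all": true},
  "grade": "high(+++)"
}
```

Read: the PT is reported 32× more often with the drug than its reporting
odds elsewhere (ROR), the observed pair count is ~18× its expectation
under independence (EBGM, = 2^IC), and all four criteria agree this is a
signal, graded high intensity because IC025 = 3.99 > 3.

The same numbers come from the library API:

```python
from faers_signals import ContingencyTable, compute_signal_stats
stats = compute_signal_stats(ContingencyTable(721, 25000, 900, 1_000_000),
                             ic_method="bate1998")
print(stats.ebgm, stats.ic)   # 17.753..., 4.1500...
```

End-to-end on synthetic data: `faers-signals simulate` renders a
configurable quarterly dataset (planted signals, duplicates, deletions,
missing dates), and `faers-signals run` executes the full pipeline,
writing `signals.tsv`, `ranked_signals.tsv`, demographic and
time-to-onset tables, subgroup outputs and a run log whose cohort funnel
reconciles exactly (raw − deleted − duplicates = cohort).

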