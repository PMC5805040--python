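# tdcea — travelers'-diarrhea deployment cost-of-illness model

Travelers' diarrhea (TD) is among the most common disease and non-battle
injury conditions in deployed military personnel (~29% incidence per
person-month), and most episodes are never seen by a provider or are treated
without antibiotics even though single-dose antibiotic + loperamide regimens
demonstrably shorten illness. `tdcea` implements a decision-tree
cost-of-illness model that quantifies what management policy changes would do
to that burden, for health-policy analysts and military preventive-medicine
planners.

Each TD episode in a deployed cohort resolves through one of eight terminal
care pathways (outpatient suboptimal/optimal/bed-rest care, untreated
run-its-course / self-treatment success / failure, hospitalization, medical
evacuation), each with a unit cost *cᵢ* (USD) and unit effectiveness loss
*dᵢ* in duty days lost (DDL). With *N* = size × months × monthly incidence
episodes per deployment-year and path probabilities *pᵢ*:

    total cost  = N · Σᵢ pᵢ cᵢ        total DDL = N · Σᵢ pᵢ dᵢ
    cost ratio  = total cost / total DDL                    (USD per DDL)
    DDL-averted = DDL_base − DDL_scenario
    CER         = (cost_scenario − cost_base) / |DDL-averted|

The package provides:

* deterministic base-case evaluation (`tdcea.evaluate`);
* three management-strategy scenarios at three implementation levels each —
  increased health-care-seeking behavior (HCSB), optimized provider
  prescribing behavior (OPB: single-dose antibiotic + loperamide), and their
  combination (`tdcea.scenarios`);
* one-way tornado sensitivity of the cost ratio and Monte Carlo
  probabilistic sensitivity analysis with triangular/truncated-normal
  distributions and median/IQR summaries (`tdcea.sensitivity`);
* an episode-level microsimulator that doubles as a brute-force oracle for
  the deterministic engine and a synthetic-data generator
  (`tdcea.microsim`);
* a JSON-configured CLI (`tdcea evaluate|scenarios|tornado|psa|simulate`).

See `docs/methods.md` for the model's assumptions, distribution conventions
and known limitations.

## Worked example

```sh
$ tdcea evaluate --out out/
episodes=50575 total_cost=$2973006 total_ddl=25918 cost_ratio=$115/DDL
```

A 50,000-person, 3.5-month deployment at 28.9% monthly incidence generates
50,575 TD episodes per deployment-year, costing the military health system
about $2.97M and 25,918 duty days lost — $115 of management cost per duty
day lost under current practice.

```sh
$ tdcea scenarios --out out/
wrote out/scenarios.csv (9 scenarios + base)
$ cat out/scenarios.csv
metric,base,hcsb_40,hcsb_55,hcsb_70,opb_65,opb_75,opb_85,combination_40_65,combination_55_75,combination_70_85
annual_episodes,50575,50575,50575,50575,50575,50575,50575,50575,50575,50575
total_cost,2973006,3401205,4043502,4685800,2660878,2622643,2584408,2985033,3401169,3779071
cost_difference,,428198,1070496,1712793,-312129,-350363,-388598,12027,428163,806064
ddl_per_year,25918,27101,30958,34816,21326,20973,20619,19584,19590,19031
ddl_averted,,-1183,-5041,-8898,4592,4945,5299,6333,6328,6887
cost_ratio,115,126,131,135,125,125,125,152,174,199
cer,,362,212,192,-68,-71,-73,2,68,117
```

Reading the columns: pushing more patients into care without improving
treatment (HCSB alone) *gains* up to 8,898 DDL per year at extra cost (CER
$192/DDL-gained); optimizing prescribing alone (OPB 85%) averts 5,299 DDL
*and* saves money (CER −$73/DDL-averted); the combination averts the most
(6,887 DDL) at a modest cost increase (CER $117/DDL-averted). A
full-precision JSON sidecar (`scenarios.json`) accompanies the rounded CSV.

```sh
$ tdcea psa --seed 1 --n 3000 --out out/
opb_85: DDL-averted median 3,910 IQR (3,047, 4,838); CER median $-96
...
```

the Monte Carlo PSA confirms OPB remains DDL-averting and cost-saving across
joint parameter uncertainty.

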