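# Default generator parameters: published age-partitioned reference quantiles
# for peripheral-blood lymphocyte subsets of healthy Chinese children (0-18 y),
# measured by single-platform flow cytometry with bead-based absolute counts.
# Each cell is [median, 2.5th percentile, 97.5th percentile]; adjacent age
# groups that the source table pooled repeat the shared triplet verbatim, so
# generated data cannot distinguish bins the source itself merged.
# Group sizes and the boy:girl ratio are the source cohort's (813 children).
age_groups:
  - {label: "0-1 month", min_months: 0, max_months: 1}
  - {label: "2-12 months", min_months: 2, max_months: 12}
  - {label: "1-3 years", min_months: 13, max_months: 47}
  - {label: "4-6 years", min_months: 48, max_months: 83}
  - {label: "7-18 years", min_months: 84, max_months: 227}
group_sizes:
  "0-1 month": 187
  "2-12 months": 154
  "1-3 years": 197
  "4-6 years": 155
  "7-18 years": 120
sex_counts: {M: 476, F: 337}
analytes:
  pct_T:
    "0-1 month": [80.59, 52.26, 89.74]
    "2-12 months": [69.10, 55.87, 82.01]
    "1-3 years": [69.10, 55.87, 82.01]
    "4-6 years": [69.10, 55.87, 82.01]
    "7-18 years": [69.10, 55.87, 82.01]
  pct_CD4:
    "0-1 month": [56.06, 28.37, 66.26]
    "2-12 months": [47.1, 28.47, 63.10]
    "1-3 years": [39.04, 27.15, 53.55]
    "4-6 years": [34.11, 22.02, 47.62]
    "7-18 years": [34.11, 22.02, 47.62]
  pct_CD8:
    "0-1 month": [18.48, 8.96, 29.11]
    "2-12 months": [18.48, 8.96, 29.11]
    "1-3 years": [21.07, 11.32, 31.93]
    "4-6 years": [22.81, 12.88, 34.17]
    "7-18 years": [22.81, 12.88, 34.17]
  ratio_CD4_CD8:
    "0-1 month": [3.16, 1.29, 7.51]
    "2-12 months": [2.52, 1.11, 5.47]
    "1-3 years": [1.88, 0.97, 3.92]
    "4-6 years": [1.50, 0.79, 3.46]
    "7-18 years": [1.50, 0.79, 3.46]
  pct_DNT:
    "0-1 month": [2.78, 0.98, 5.16]
    "2-12 months": [5.88, 3.01, 23.37]
    "1-3 years": [10.95, 4.31, 25.52]
    "4-6 years": [13.55, 5.65, 26.44]
    "7-18 years": [13.55, 5.65, 26.44]
  pct_B:
    "0-1 month": [9.84, 3.56, 21.33]
    "2-12 months": [18.96, 10.25, 31.88]
    "1-3 years": [18.96, 10.25, 31.88]
    "4-6 years": [17.00, 8.70, 29.21]
    "7-18 years": [14.31, 6.77, 30.41]
  pct_NK:
    "0-1 month": [2.51, 0.76, 14.31]
    "2-12 months": [4.12, 1.07, 12.23]
    "1-3 years": [5.11, 1.59, 20.01]
    "4-6 years": [7.92, 2.33, 19.46]
    "7-18 years": [9.96, 1.44, 25.51]
  pct_NKT:
    "0-1 month": [0.64, 0.16, 3.20]
    "2-12 months": [0.64, 0.16, 3.20]
    "1-3 years": [0.93, 0.23, 2.91]
    "4-6 years": [1.22, 0.25, 3.65]
    "7-18 years": [2.04, 0.33, 6.19]
  cnt_lymph:
    "0-1 month": [3028, 1136, 6541]
    "2-12 months": [4498, 2309, 7003]
    "1-3 years": [3687, 1615, 7096]
    "4-6 years": [2844, 1450, 5771]
    "7-18 years": [2043, 1226, 4767]
  cnt_T:
    "0-1 month": [2333, 1042, 5134]
    "2-12 months": [3039, 1612, 5230]
    "1-3 years": [2603, 1020, 4752]
    "4-6 years": [2018, 998, 3975]
    "7-18 years": [1382, 812, 3139]
  cnt_CD4:
    "0-1 month": [1647, 326, 3320]
    "2-12 months": [2028, 929, 3857]
    "1-3 years": [1410, 484, 2809]
    "4-6 years": [996, 420, 1974]
    "7-18 years": [638, 373.2, 1920]
  cnt_CD8:
    "0-1 month": [505, 150, 1550]
    "2-12 months": [757, 256, 1663]
    "1-3 years": [697, 266, 1637]
    "4-6 years": [637, 235, 1576]
    "7-18 years": [454, 216, 1305]
  cnt_DNT:
    "0-1 month": [62, 23, 170]
    "2-12 months": [185, 86, 531]
    "1-3 years": [266, 113, 581]
    "4-6 years": [266, 113, 581]
    "7-18 years": [190, 66, 532]
  cnt_B:
    "0-1 month": [292, 85, 737]
    "2-12 months": [912, 149, 2073]
    "1-3 years": [729, 236, 1785]
    "4-6 years": [473, 158, 1201]
    "7-18 years": [292, 109, 1603]
  cnt_NK:
    "0-1 month": [82, 24, 665]
    "2-12 months": [210, 60, 660]
    "1-3 years": [210, 60, 660]
    "4-6 years": [210, 60, 660]
    "7-18 years": [210, 60, 660]
  cnt_NKT:
    "0-1 month": [19, 6, 94]
    "2-12 months": [35, 9, 119]
    "1-3 years": [35, 9, 119]
    "4-6 years": [35, 9, 119]
    "7-18 years": [35, 9, 119]
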