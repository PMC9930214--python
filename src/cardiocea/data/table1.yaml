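# Base-case parameter set for the CABG vs drug-eluting-stent PCI Markov model.
# Each entry carries the point value and its low-high range (treated as a 95% CI
# when fitting probabilistic-sensitivity-analysis distributions).
settings:
  annual_discount_rate: 0.03
  cycle_length_years: 0.5
  entry_age_years: 59

probabilities:
  cabg:
    stable:      {value: 0.9476, low: 0.85284, high: 1.04236}
    repeat_cabg: {value: 0.006,  low: 0.0054,  high: 0.0066}
    repeat_pci:  {value: 0.005,  low: 0.0045,  high: 0.0055}
    cva:         {value: 0.001,  low: 0.0009,  high: 0.0011}
    cad_death:   {value: 0.0371, low: 0.03339, high: 0.04081}
    other_death: {value: 0.003,  low: 0.0027,  high: 0.0033}
  pci:
    stable:      {value: 0.7813, low: 0.70317, high: 0.85943}
    repeat_cabg: {value: 0.1505, low: 0.13545, high: 0.16555}
    repeat_pci:  {value: 0.0537, low: 0.04833, high: 0.05907}
    cva:         {value: 0.0071, low: 0.00639, high: 0.00781}
    cad_death:   {value: 0.0035, low: 0.00315, high: 0.00385}
    other_death: {value: 0.0035, low: 0.00315, high: 0.00385}
  shared:
    cad_death_after_stable: {value: 0.009, low: 0.008, high: 0.012}
    cad_death_after_cva:    {value: 0.074, low: 0.059, high: 0.089}
    death_other_causes:     {value: 0.004, low: 0.004, high: 0.006}

utilities:
  saq:
    cabg:
      stable:      {value: 0.135, low: 0.108, high: 0.163}
      repeat_cabg: {value: 0.158, low: 0.126, high: 0.189}
      repeat_pci:  {value: 0.105, low: 0.084, high: 0.126}
      cva:         {value: 0.390, low: 0.312, high: 0.468}
    pci:
      stable:      {value: 0.063, low: 0.050, high: 0.075}
      repeat_cabg: {value: -0.357, low: -0.3928, high: -0.3214}
      repeat_pci:  {value: 0.079, low: 0.063, high: 0.094}
      cva:         {value: 0.390, low: 0.312, high: 0.468}
  sf36:
    cabg:
      stable:      {value: 0.100, low: 0.080, high: 0.120}
      repeat_cabg: {value: 0.154, low: 0.123, high: 0.185}
      repeat_pci:  {value: 0.139, low: 0.111, high: 0.167}
      cva:         {value: 0.390, low: 0.312, high: 0.468}
    pci:
      stable:      {value: 0.063, low: 0.050, high: 0.076}
      repeat_cabg: {value: -0.008, low: -0.009, high: -0.006}
      repeat_pci:  {value: 0.107, low: 0.085, high: 0.128}
      cva:         {value: 0.390, low: 0.312, high: 0.468}

costs:
  cabg:
    stable:      {value: 2426, low: 1941, high: 2912}
    repeat_cabg: {value: 1880, low: 1504, high: 2256}
    repeat_pci:  {value: 1128, low: 903,  high: 1354}
    cva:         {value: 323,  low: 259,  high: 388}
    cad_death:   {value: 3931, low: 3144, high: 4717}
    other_death: {value: 5700, low: 4560, high: 6841}
  pci:
    stable:      {value: 3193, low: 2555, high: 3832}
    repeat_cabg: {value: 2086, low: 1669, high: 2503}
    repeat_pci:  {value: 3365, low: 2692, high: 4038}
    cva:         {value: 723,  low: 578,  high: 867}
    cad_death:   {value: 4219, low: 3375, high: 5062}
    other_death: {value: 4219, low: 3375, high: 5062}
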