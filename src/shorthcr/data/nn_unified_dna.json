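{
 "name": "unified-dna-nn",
 "version": 1,
 "temperature_K": 310.15,
 "conditions": "1 M NaCl, pH 7; 37 C convention",
 "source": "unified oligonucleotide nearest-neighbor parameters (SantaLucia 1998; SantaLucia & Hicks 2004); DNA hairpin-loop penalties from the same compilation, log-extrapolated beyond size 9",
 "units": {
  "dH": "kcal/mol",
  "dS": "cal/(mol*K)",
  "dG37": "kcal/mol"
 },
 "stack_dH": {
  "AA": -7.9,
  "AT": -7.2,
  "TA": -7.2,
  "CA": -8.5,
  "GT": -8.4,
  "CT": -7.8,
  "GA": -8.2,
  "CG": -10.6,
  "GC": -9.8,
  "GG": -8.0
 },
 "stack_dS": {
  "AA": -22.2,
  "AT": -20.4,
  "TA": -21.3,
  "CA": -22.7,
  "GT": -22.4,
  "CT": -21.0,
  "GA": -22.2,
  "CG": -27.2,
  "GC": -24.4,
  "GG": -19.9
 },
 "init_dH": 0.2,
 "init_dS": -5.7,
 "terminal_AT_dH": 2.2,
 "terminal_AT_dS": 6.9,
 "hairpin_loop_dG37": {
  "3": 3.5,
  "4": 3.5,
  "5": 3.3,
  "6": 4.0,
  "7": 4.2,
  "8": 4.3,
  "9": 4.5,
  "10": 4.61,
  "11": 4.72,
  "12": 4.81,
  "13": 4.9,
  "14": 4.98,
  "15": 5.05,
  "16": 5.12,
  "17": 5.19,
  "18": 5.25,
  "19": 5.31,
  "20": 5.36,
  "21": 5.41,
  "22": 5.46,
  "23": 5.51,
  "24": 5.56,
  "25": 5.6,
  "26": 5.64,
  "27": 5.68,
  "28": 5.72,
  "29": 5.76,
  "30": 5.8
 },
 "loop_extrapolation": {
  "rule": "dG(n) = dG(30) + 1.75*R*T*ln(n/30) for n > 30",
  "R": 0.0019872
 }
}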