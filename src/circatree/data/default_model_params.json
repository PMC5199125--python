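{
 "clock": {
  "b": 0.1,
  "A": 2.0,
  "omega": 0.2617993877991494
 },
 "sigc": {
  "gene": {
   "V": 1.648,
   "act": {
    "K": 1.4801,
    "h": 4.0
   },
   "rep": {
    "K": 1.7028,
    "h": 2.0
   },
   "gamma": 0.5423
  },
  "k_act": 0.9382,
  "k_deact": 0.0764
 },
 "psbai": {
  "V": 1.0,
  "act": {
   "K": 0.6728,
   "h": 4.0
  },
  "rep": {
   "K": 1.1546,
   "h": 4.0
  },
  "gamma": 0.6893
 },
 "rpod6": {
  "V": 1.0,
  "act": {
   "K": 1.0818,
   "h": 4.0
  },
  "rep": {
   "K": 1.1546,
   "h": 4.0
  },
  "gamma": 0.6893
 }
}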