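{
 "hypothesis": "interference",
 "params": {
  "k1": 2.876702805778082,
  "k2": 4.496995201315975,
  "k3": 1.2988798513050406,
  "k4": 2.1699849500642925,
  "k5": 7.2477453852821405,
  "k6": 0.7717740852020485,
  "k7": 0.07099669804228191,
  "K": 3.1385969532033613,
  "n": 14.493898587546571,
  "t1": 2.6234674118448496,
  "s1": 2.138855188886127,
  "t2": 0.7170701307795371,
  "s2": 4.202855089244851,
  "t3": 6.79902253000187,
  "s3": 1.0409182893015891,
  "t4": 1.7267784876980192,
  "s4": 2.5176476044653553,
  "dW": 0.6640605803282712,
  "kW": 8.393012206931743,
  "k3_weak": 0.0,
  "k8": 3.799017996013804
 }
}
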