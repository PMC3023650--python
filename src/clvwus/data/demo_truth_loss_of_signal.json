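{
 "hypothesis": "loss_of_signal",
 "params": {
  "k1": 3.048600666086915,
  "k2": 6.121630953016628,
  "k3": 8.9036027127286,
  "k4": 5.41193868343182,
  "k5": 5.027961320930782,
  "k6": 12.472046062708806,
  "k7": 12.911027582217342,
  "K": 14.581637957496682,
  "n": 7.907076343923909,
  "t1": 10.547325279155123,
  "s1": 11.780780479468545,
  "t2": 0.9469163225699887,
  "s2": 1.7199714285888024,
  "t3": 9.946998195719413,
  "s3": 2.7748428996240686,
  "t4": 2.6874848652174483,
  "s4": 5.6417590436129545,
  "dW": 15.00063793781741,
  "kW": 1.089292964805995,
  "k3_weak": 2.0065818390023784,
  "k8": 0.0
 }
}
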