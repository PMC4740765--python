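{
 "DYS19": {
  "counts": {
   "13": 10,
   "14": 27,
   "15": 44,
   "16": 11,
   "17": 9
  },
  "n": 101,
  "n_samples": 100,
  "gd_printed": "0.7163"
 },
 "DYS389I": {
  "counts": {
   "12": 16,
   "13": 47,
   "14": 36,
   "15": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6301"
 },
 "DYS389II": {
  "counts": {
   "27": 2,
   "28": 10,
   "29": 28,
   "30": 33,
   "31": 18,
   "32": 9
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7695"
 },
 "DYS390": {
  "counts": {
   "19": 3,
   "20": 1,
   "21": 0,
   "22": 7,
   "23": 32,
   "24": 29,
   "25": 25,
   "26": 3
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7517"
 },
 "DYS391": {
  "counts": {
   "9": 3,
   "10": 62,
   "11": 35
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.4972"
 },
 "DYS392": {
  "counts": {
   "7": 5,
   "10": 2,
   "11": 46,
   "12": 2,
   "13": 23,
   "14": 17,
   "15": 3,
   "16": 2
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7091"
 },
 "DYS393": {
  "counts": {
   "11": 1,
   "12": 34,
   "13": 53,
   "14": 10,
   "15": 2
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.5990"
 },
 "DYS385ab": {
  "counts": {
   "9": 2,
   "10": 1,
   "11": 38,
   "12": 19,
   "13": 28,
   "14": 35,
   "15": 16,
   "16": 16,
   "17": 13,
   "18": 6,
   "19": 2,
   "20": 6,
   "21": 2,
   "22": 1,
   "24": 1
  },
  "n": 186,
  "n_samples": null,
  "gd_printed": "0.8763"
 },
 "DYS437": {
  "counts": {
   "13": 3,
   "14": 57,
   "15": 33,
   "16": 7
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.5661"
 },
 "DYS438": {
  "counts": {
   "9": 8,
   "10": 41,
   "11": 40,
   "12": 10,
   "13": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6620"
 },
 "DYS439": {
  "counts": {
   "10": 30,
   "11": 24,
   "12": 32,
   "13": 12,
   "14": 2
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7426"
 },
 "DYS448": {
  "counts": {
   "16": 1,
   "18": 8,
   "19": 42,
   "20": 37,
   "21": 9,
   "22": 2,
   "null": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6784"
 },
 "DYS456": {
  "counts": {
   "13": 1,
   "14": 13,
   "15": 55,
   "16": 22,
   "17": 7,
   "18": 2
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6331"
 },
 "DYS458": {
  "counts": {
   "14": 4,
   "15": 28,
   "16": 20,
   "17": 19,
   "18": 17,
   "19": 5,
   "20": 6,
   "21": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.8170"
 },
 "DYS635": {
  "counts": {
   "19": 5,
   "20": 7,
   "21": 29,
   "22": 20,
   "23": 28,
   "24": 9,
   "26": 1,
   "27": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7897"
 },
 "Y_GATA_H4": {
  "counts": {
   "10": 6,
   "11": 42,
   "12": 34,
   "13": 17,
   "14": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6822"
 },
 "DYS576": {
  "counts": {
   "13": 1,
   "14": 1,
   "15": 2,
   "16": 12,
   "17": 27,
   "18": 33,
   "19": 17,
   "20": 6,
   "21": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7784"
 },
 "DYS570": {
  "counts": {
   "13": 1,
   "14": 2,
   "15": 1,
   "16": 14,
   "17": 24,
   "18": 21,
   "19": 22,
   "20": 11,
   "21": 3,
   "24": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.8248"
 },
 "DYS481": {
  "counts": {
   "19": 1,
   "20": 4,
   "21": 5,
   "22": 12,
   "23": 26,
   "24": 21,
   "25": 21,
   "26": 6,
   "27": 3,
   "28": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.8293"
 },
 "DYS533": {
  "counts": {
   "9": 1,
   "10": 7,
   "11": 34,
   "12": 49,
   "13": 8,
   "14": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6392"
 },
 "DYS549": {
  "counts": {
   "10": 1,
   "11": 10,
   "12": 48,
   "13": 29,
   "14": 10,
   "15": 2
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6717"
 },
 "DYS643": {
  "counts": {
   "8": 4,
   "9": 13,
   "10": 44,
   "11": 25,
   "12": 11,
   "13": 1,
   "14": 1,
   "null": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.7202"
 },
 "DYS460": {
  "counts": {
   "9": 14,
   "10": 35,
   "11": 46,
   "12": 5
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.6503"
 },
 "DYS449": {
  "counts": {
   "25": 1,
   "26": 2,
   "27": 5,
   "28": 3,
   "29": 11,
   "30": 15,
   "31": 20,
   "32": 27,
   "33": 11,
   "34": 3,
   "34.1": 1,
   "35": 2
  },
  "n": 101,
  "n_samples": 100,
  "gd_printed": "0.8472"
 },
 "DYS388": {
  "counts": {
   "10": 3,
   "12": 79,
   "13": 6,
   "14": 9,
   "15": 2,
   "16": 1
  },
  "n": 100,
  "n_samples": 100,
  "gd_printed": "0.3665"
 }
}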