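field,MLP41 Lipids,MLP41 TAG,"MLP41 1,2-DAG","MLP41 1,3-DAG",MLG23 Lipids,MLG23 TAG,"MLG23 1,2-DAG","MLG23 1,3-DAG",MLY23 Lipids,MLY23 TAG,"MLY23 1,2-DAG","MLY23 1,3-DAG",MLY31W Lipids,MLY31W TAG,"MLY31W 1,2-DAG","MLY31W 1,3-DAG",MLGP11 Lipids,MLGP11 TAG,"MLGP11 1,2-DAG","MLGP11 1,3-DAG"
C16+C18,98.03,98.81,98.88,100.00,97.29,96.71,99.36,99.57,98.43,95.22,95.22,96.80,97.84,97.31,100.00,99.51,94.07,94.42,99.02,100.00
SFA,34.39,39.72,32.92,40.18,27.38,35.19,35.49,35.12,42.69,47.32,56.92,57.93,41.43,48.19,31.02,32.33,36.74,46.35,38.49,39.03
MUFA,39.80,36.24,42.94,46.69,39.09,35.85,33.42,36.45,41.26,35.65,38.56,32.20,39.05,38.92,45.69,57.44,28.95,26.79,36.11,30.81
PUFA,25.81,24.04,24.14,13.13,33.53,28.96,31.09,28.43,16.05,17.03,5.24,9.87,19.52,12.89,23.29,10.23,34.30,26.86,25.40,30.16
UFA,65.61,60.28,67.08,59.82,72.62,64.81,64.51,64.88,57.31,52.68,43.80,42.07,58.57,51.81,68.98,67.67,63.26,53.65,61.51,60.97
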