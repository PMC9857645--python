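fa,MLP41 Lipids,MLP41 TAG,"MLP41 1,2-DAG","MLP41 1,3-DAG",MLG23 Lipids,MLG23 TAG,"MLG23 1,2-DAG","MLG23 1,3-DAG",MLY23 Lipids,MLY23 TAG,"MLY23 1,2-DAG","MLY23 1,3-DAG",MLY31W Lipids,MLY31W TAG,"MLY31W 1,2-DAG","MLY31W 1,3-DAG",MLGP11 Lipids,MLGP11 TAG,"MLGP11 1,2-DAG","MLGP11 1,3-DAG"
C14:0,0.41,0.36,1.12,nd,0.003,0.51,nd,nd,0.56,1.25,3.08,1.74,0.42,nd,nd,0.49,0.54,0.18,nd,nd
C15:0,0.31,0.53,nd,nd,0.43,0.81,0.64,0.43,nd,0.37,1.70,1.46,nd,nd,nd,nd,1.73,1.04,0.98,nd
C16:0,21.58,28.45,20.24,24.82,19.08,25.21,27.82,25.97,31.97,31.61,35.11,34.13,29.09,34.24,21.80,19.15,17.63,24.55,23.33,24.43
C16:1,1.14,2.04,2.38,nd,0.77,1.93,2.30,1.46,0.85,2.10,7.22,5.43,0.44,nd,nd,1.62,1.44,0.77,2.11,2.01
C17:0,0.08,nd,nd,nd,0.40,0.52,nd,nd,nd,nd,nd,nd,nd,nd,nd,nd,1.25,0.33,nd,nd
C17:1,nd,nd,nd,nd,0.59,1.37,nd,nd,nd,nd,nd,nd,nd,nd,nd,nd,0.70,nd,nd,nd
C18:0,10.93,10.07,11.56,15.36,7.15,8.07,7.03,8.71,9.15,10.93,16.31,20.61,10.18,11.26,9.22,12.69,13.88,17.42,14.18,14.59
C18:1,38.66,34.20,40.56,46.69,36.76,32.55,31.12,34.99,40.41,33.55,31.34,26.77,38.61,38.92,45.69,55.82,26.82,26.81,34.00,28.80
C18:2,25.81,24.04,24.14,13.13,32.12,28.96,31.09,28.43,14.71,14.83,5.24,9.87,19.52,12.89,23.29,10.23,34.30,27.65,25.40,30.16
C18:3,nd,nd,nd,nd,1.41,nd,nd,nd,1.34,2.20,nd,nd,nd,nd,nd,nd,nd,nd,nd,nd
C20:0,0.46,0.09,nd,nd,0.32,0.08,nd,nd,0.46,1.47,nd,nd,1.16,2.09,nd,nd,1.72,0.53,nd,nd
C22:0,0.61,0.21,nd,nd,nd,nd,nd,nd,0.55,1.69,nd,nd,0.58,0.60,nd,nd,nd,0.71,nd,nd
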