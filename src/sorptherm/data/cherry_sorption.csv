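sample_id,mode,temperature_c,aw,xeq_percent_db
Burlat,desorption,30,0.0738,14.47
Burlat,desorption,30,0.3238,17.12
Burlat,desorption,30,0.4317,22.15
Burlat,desorption,30,0.7275,48.23
Burlat,desorption,30,0.8362,78.77
Burlat,desorption,30,0.898,92.88
Burlat,desorption,40,0.0626,10.4
Burlat,desorption,40,0.3259,13.08
Burlat,desorption,40,0.423,16.5
Burlat,desorption,40,0.71,39.35
Burlat,desorption,40,0.8232,65.93
Burlat,desorption,40,0.891,76.14
Burlat,desorption,50,0.0572,6.83
Burlat,desorption,50,0.3054,9.61
Burlat,desorption,50,0.4091,15.43
Burlat,desorption,50,0.6904,36.66
Burlat,desorption,50,0.812,57.29
Burlat,desorption,50,0.8823,60.05
Burlat,adsorption,30,0.0738,13.46
Burlat,adsorption,30,0.3238,15.48
Burlat,adsorption,30,0.4317,19.96
Burlat,adsorption,30,0.7275,39.35
Burlat,adsorption,30,0.8362,71.78
Burlat,adsorption,30,0.898,84.49
Burlat,adsorption,40,0.0626,8.14
Burlat,adsorption,40,0.3259,10.53
Burlat,adsorption,40,0.423,11.59
Burlat,adsorption,40,0.71,33.22
Burlat,adsorption,40,0.8232,60.19
Burlat,adsorption,40,0.891,68.33
Burlat,adsorption,50,0.0572,5.23
Burlat,adsorption,50,0.3054,7.05
Burlat,adsorption,50,0.4091,10.95
Burlat,adsorption,50,0.6904,26.56
Burlat,adsorption,50,0.812,52.7
Burlat,adsorption,50,0.8823,53.45
Van,desorption,30,0.0738,13.18
Van,desorption,30,0.3238,16.83
Van,desorption,30,0.4317,32.26
Van,desorption,30,0.7275,37.23
Van,desorption,30,0.8362,52.33
Van,desorption,30,0.898,92.91
Van,desorption,40,0.0626,12.79
Van,desorption,40,0.3259,16.74
Van,desorption,40,0.423,19.4
Van,desorption,40,0.71,27.99
Van,desorption,40,0.8232,45.68
Van,desorption,40,0.891,48.15
Van,desorption,50,0.0572,11.84
Van,desorption,50,0.3054,9.39
Van,desorption,50,0.4091,14.51
Van,desorption,50,0.6904,25.94
Van,desorption,50,0.812,42.86
Van,desorption,50,0.8823,44.28
Van,adsorption,30,0.0738,11.31
Van,adsorption,30,0.3238,13.33
Van,adsorption,30,0.4317,24.78
Van,adsorption,30,0.7275,33.34
Van,adsorption,30,0.8362,50.72
Van,adsorption,30,0.898,85.0
Van,adsorption,40,0.0626,6.32
Van,adsorption,40,0.3259,12.38
Van,adsorption,40,0.423,15.5
Van,adsorption,40,0.71,25.24
Van,adsorption,40,0.8232,35.24
Van,adsorption,40,0.891,42.59
Van,adsorption,50,0.0572,4.43
Van,adsorption,50,0.3054,10.64
Van,adsorption,50,0.4091,13.7
Van,adsorption,50,0.6904,17.74
Van,adsorption,50,0.812,31.25
Van,adsorption,50,0.8823,40.93
Napoleon,desorption,30,0.0738,14.15
Napoleon,desorption,30,0.3238,22.6
Napoleon,desorption,30,0.4317,27.96
Napoleon,desorption,30,0.7275,42.21
Napoleon,desorption,30,0.8362,52.96
Napoleon,desorption,30,0.898,91.44
Napoleon,desorption,40,0.0626,10.36
Napoleon,desorption,40,0.3259,19.74
Napoleon,desorption,40,0.423,23.7
Napoleon,desorption,40,0.71,34.97
Napoleon,desorption,40,0.8232,49.04
Napoleon,desorption,40,0.891,69.64
Napoleon,desorption,50,0.0572,8.66
Napoleon,desorption,50,0.3054,18.18
Napoleon,desorption,50,0.4091,21.34
Napoleon,desorption,50,0.6904,33.57
Napoleon,desorption,50,0.812,41.46
Napoleon,desorption,50,0.8823,53.91
Napoleon,adsorption,30,0.0738,13.7
Napoleon,adsorption,30,0.3238,20.81
Napoleon,adsorption,30,0.4317,26.41
Napoleon,adsorption,30,0.7275,41.41
Napoleon,adsorption,30,0.8362,48.76
Napoleon,adsorption,30,0.898,71.93
Napoleon,adsorption,40,0.0626,8.54
Napoleon,adsorption,40,0.3259,17.44
Napoleon,adsorption,40,0.423,22.85
Napoleon,adsorption,40,0.71,31.96
Napoleon,adsorption,40,0.8232,47.8
Napoleon,adsorption,40,0.891,66.48
Napoleon,adsorption,50,0.0572,7.09
Napoleon,adsorption,50,0.3054,16.71
Napoleon,adsorption,50,0.4091,21.19
Napoleon,adsorption,50,0.6904,32.31
Napoleon,adsorption,50,0.812,39.28
Napoleon,adsorption,50,0.8823,51.21
Cerisette,desorption,30,0.0738,13.01
Cerisette,desorption,30,0.3238,14.16
Cerisette,desorption,30,0.4317,17.47
Cerisette,desorption,30,0.7275,48.21
Cerisette,desorption,30,0.8362,53.63
Cerisette,desorption,30,0.898,96.63
Cerisette,desorption,40,0.0626,11.81
Cerisette,desorption,40,0.3259,13.3
Cerisette,desorption,40,0.423,16.21
Cerisette,desorption,40,0.71,43.31
Cerisette,desorption,40,0.8232,49.25
Cerisette,desorption,40,0.891,74.57
Cerisette,desorption,50,0.0572,7.31
Cerisette,desorption,50,0.3054,12.9
Cerisette,desorption,50,0.4091,15.69
Cerisette,desorption,50,0.6904,29.45
Cerisette,desorption,50,0.812,46.91
Cerisette,desorption,50,0.8823,70.05
Cerisette,adsorption,30,0.0738,11.72
Cerisette,adsorption,30,0.3238,13.57
Cerisette,adsorption,30,0.4317,16.31
Cerisette,adsorption,30,0.7275,44.47
Cerisette,adsorption,30,0.8362,52.54
Cerisette,adsorption,30,0.898,85.98
Cerisette,adsorption,40,0.0626,8.14
Cerisette,adsorption,40,0.3259,12.77
Cerisette,adsorption,40,0.423,15.37
Cerisette,adsorption,40,0.71,38.68
Cerisette,adsorption,40,0.8232,46.53
Cerisette,adsorption,40,0.891,68.8
Cerisette,adsorption,50,0.0572,7.8
Cerisette,adsorption,50,0.3054,11.78
Cerisette,adsorption,50,0.4091,14.72
Cerisette,adsorption,50,0.6904,24.26
Cerisette,adsorption,50,0.812,43.99
Cerisette,adsorption,50,0.8823,67.01
Coeur pigeon,desorption,30,0.0738,7.21
Coeur pigeon,desorption,30,0.3238,11.18
Coeur pigeon,desorption,30,0.4317,16.53
Coeur pigeon,desorption,30,0.7275,43.96
Coeur pigeon,desorption,30,0.8362,57.49
Coeur pigeon,desorption,30,0.898,88.43
Coeur pigeon,desorption,40,0.0626,8.4
Coeur pigeon,desorption,40,0.3259,10.63
Coeur pigeon,desorption,40,0.423,14.29
Coeur pigeon,desorption,40,0.71,43.42
Coeur pigeon,desorption,40,0.8232,53.36
Coeur pigeon,desorption,40,0.891,80.49
Coeur pigeon,desorption,50,0.0572,8.01
Coeur pigeon,desorption,50,0.3054,9.63
Coeur pigeon,desorption,50,0.4091,13.58
Coeur pigeon,desorption,50,0.6904,41.45
Coeur pigeon,desorption,50,0.812,49.43
Coeur pigeon,desorption,50,0.8823,79.72
Coeur pigeon,adsorption,30,0.0738,7.19
Coeur pigeon,adsorption,30,0.3238,11.04
Coeur pigeon,adsorption,30,0.4317,15.66
Coeur pigeon,adsorption,30,0.7275,42.98
Coeur pigeon,adsorption,30,0.8362,55.5
Coeur pigeon,adsorption,30,0.898,81.4
Coeur pigeon,adsorption,40,0.0626,6.24
Coeur pigeon,adsorption,40,0.3259,10.13
Coeur pigeon,adsorption,40,0.423,13.44
Coeur pigeon,adsorption,40,0.71,37.16
Coeur pigeon,adsorption,40,0.8232,46.18
Coeur pigeon,adsorption,40,0.891,67.29
Coeur pigeon,adsorption,50,0.0572,5.75
Coeur pigeon,adsorption,50,0.3054,9.99
Coeur pigeon,adsorption,50,0.4091,16.68
Coeur pigeon,adsorption,50,0.6904,34.99
Coeur pigeon,adsorption,50,0.812,43.73
Coeur pigeon,adsorption,50,0.8823,65.75
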