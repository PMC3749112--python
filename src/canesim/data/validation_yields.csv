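site,lit_yield,model_yield,tmax,tmin,precip,latitude,longitude
"Auburn, AL",26.1,25.4,24.2,9.8,1160,32.67,-85.44
"Belle Glade, FL",25.0,28.3,27.8,16.4,1378,26.68,-80.67
"EREC, FL",51.3,43.5,29.1,17.7,1181,26.65,-80.63
"Gainesville, FL",35.6,27.3,27.0,13.7,1123,29.68,-82.27
"Hendry, FL",39.2,55.9,28.4,18.3,1362,27.78,-82.15
"Hillsboro, FL",60.7,62.5,28.5,18.3,1547,27.90,-82.49
"Houma, LA (1st ratoon)",36.6,38.2,25.2,14.8,500,29.57,-90.65
"Houma, LA (2nd ratoon)",34.9,37.6,25.2,14.8,500,29.57,-90.65
"Hundley, FL",73.5,62.0,28.5,18.1,1457,26.30,-80.16
"Jay, FL (plant cane)",35.8,33.6,26.9,16.4,1321,28.65,-80.82
"Jay, FL (1st ratoon)",27.8,32.8,26.9,16.4,1321,28.65,-80.82
"Lakeview, FL",71.3,62.5,28.5,17.4,1275,26.30,-80.15
"Hidalgo, TX",34.6,42.5,28.7,18.1,576,26.17,-97.93
"Ona, FL (1st ratoon)",40.5,38.1,28.6,16.0,1160,27.48,-81.92
"Ona, FL (2nd ratoon)",30.2,31.6,28.6,16.0,1160,27.48,-81.92
"Pahokee, FL",60.5,65.5,28.4,17.5,1269,26.82,-80.66
"Palm Beach, FL",32.3,35.4,29.0,16.6,851,26.67,-80.15
"Quincy, FL (1st ratoon)",26.3,25.1,25.8,12.9,1445,30.59,-84.58
"Quincy, FL (2nd ratoon)",27.8,21.7,25.8,12.9,1445,30.59,-84.58
"Shorter, AL",26.4,25.4,24.9,10.9,1119,32.40,-85.94
"Sundance, FL",42.1,43.5,28.6,17.5,1303,26.60,-80.87
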