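SMITH
JOHNSON
WILLIAMS
BROWN
JONES
GARCIA
MILLER
DAVIS
RODRIGUEZ
MARTINEZ
HERNANDEZ
LOPEZ
GONZALEZ
WILSON
ANDERSON
THOMAS
TAYLOR
MOORE
JACKSON
MARTIN
LEE
PEREZ
THOMPSON
WHITE
HARRIS
SANCHEZ
CLARK
RAMIREZ
LEWIS
ROBINSON
WALKER
YOUNG
ALLEN
KING
WRIGHT
SCOTT
TORRES
NGUYEN
HILL
FLORES
GREEN
ADAMS
NELSON
BAKER
HALL
RIVERA
CAMPBELL
MITCHELL
CARTER
ROBERTS
GOMEZ
PHILLIPS
EVANS
TURNER
DIAZ
PARKER
CRUZ
EDWARDS
COLLINS
REYES
STEWART
MORRIS
MORALES
MURPHY
COOK
ROGERS
GUTIERREZ
ORTIZ
MORGAN
COOPER
PETERSON
BAILEY
REED
KELLY
HOWARD
RAMOS
KIM
COX
WARD
RICHARDSON
WATSON
BROOKS
CHAVEZ
WOOD
JAMES
BENNETT
GRAY
MENDOZA
RUIZ
HUGHES
PRICE
ALVAREZ
CASTILLO
SANDERS
PATEL
MYERS
LONG
ROSS
FOSTER
JIMENEZ
POWELL
JENKINS
PERRY
RUSSELL
SULLIVAN
BELL
COLEMAN
BUTLER
HENDERSON
BARNES
GONZALES
FISHER
VASQUEZ
SIMMONS
ROMERO
JORDAN
PATTERSON
ALEXANDER
HAMILTON
GRAHAM
REYNOLDS
GRIFFIN
WALLACE
MORENO
WEST
COLE
HAYES
BRYANT
HERRERA
GIBSON
ELLIS
TRAN
MEDINA
AGUILAR
STEVENS
MURRAY
FORD
CASTRO
MARSHALL
OWENS
HARRISON
FERNANDEZ
MCDONALD
WOODS
WASHINGTON
KENNEDY
WELLS
VARGAS
HENRY
CHEN
FREEMAN
WEBB
TUCKER
GUZMAN
BURNS
CRAWFORD
OLSON
SIMPSON
PORTER
HUNTER
GORDON
MENDEZ
SILVA
SHAW
SNYDER
MASON
DIXON
MUNOZ
HUNT
HICKS
HOLMES
PALMER
WAGNER
BLACK
ROBERTSON
BOYD
ROSE
STONE
SALAZAR
FOX
WARREN
MILLS
MEYER
RICE
SCHMIDT
GARZA
DANIELS
FERGUSON
NICHOLS
STEPHENS
SOTO
WEAVER
RYAN
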